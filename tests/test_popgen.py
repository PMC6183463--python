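"""Population-genetic statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinekit import popgen
from clinekit import simulate as sim
from clinekit.gio import GenotypeMatrix


def _biallelic_matrix(genos_by_site):
    """Build a one-locus matrix from per-site genotype count triples
    (n_hom_ref, n_het, n_hom_alt)."""
    rows, ids, sites = [], [], []
    for site, (n2, n1, n0) in genos_by_site.items():
        for g, n in zip(((1, 1), (1, 2), (2, 2)), (n2, n1, n0)):
            for _ in range(n):
                rows.append([g])
                ids.append(f"{site}{len(ids)}")
                sites.append(site)
    inds = pd.DataFrame({"id": ids, "site": sites})
    loci = pd.DataFrame({"name": ["L1"], "kind": ["snp"], "ploidy": [2]})
    return GenotypeMatrix(inds, loci, np.array(rows))


def _wc_theta_oracle(n1, p1, h1, n2, p2, h2):
    """Independent transcription of the 1984 two-population variance
    components for one biallelic locus (both alleles accumulated)."""
    num = den = 0.0
    for p1a, p2a, share in (((p1, p2, 1)), ((1 - p1, 1 - p2, 1))):
        nbar = (n1 + n2) / 2
        nc = (2 * nbar - (n1 * n1 + n2 * n2) / (2 * nbar))
        pbar = (n1 * p1a + n2 * p2a) / (2 * nbar)
        s2 = (n1 * (p1a - pbar) ** 2 + n2 * (p2a - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestWeirCockerham:
    def test_toy_table_matches_hand_computation(self):
        """n=10 each; 18/2 vs 6/14 reference-allele copies."""
        m = _biallelic_matrix({"A": (8, 2, 0), "B": (1, 4, 5)})
        est = popgen.weir_cockerham_fst(m, "A", "B")
        oracle = _wc_theta_oracle(10, 18 / 20, 2 / 10, 10, 6 / 20, 4 / 10)
        assert est == pytest.approx(oracle, abs=1e-12)

    def test_fixed_differences_give_one(self):
        m = _biallelic_matrix({"A": (10, 0, 0), "B": (0, 0, 10)})
        assert popgen.weir_cockerham_fst(m, "A", "B") == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, rng):
        p = rng.uniform(0.2, 0.8, 60)
        g = rng.binomial(2, p, size=(200, 60))
        alleles = np.zeros((200, 60, 2), dtype=int)
        alleles[:, :, 0] = np.where(g >= 1, 1, 2)
        alleles[:, :, 1] = np.where(g == 2, 1, 2)
        inds = pd.DataFrame({"id": [f"i{k}" for k in range(200)],
                             "site": ["A"] * 100 + ["B"] * 100})
        loci = pd.DataFrame({"name": [f"L{j}" for j in range(60)],
                             "kind": "snp", "ploidy": 2})
        m = GenotypeMatrix(inds, loci, alleles)
        assert abs(popgen.weir_cockerham_fst(m, "A", "B")) < 0.01

    def test_no_shared_polymorphic_loci_is_undefined(self):
        m = _biallelic_matrix({"A": (5, 0, 0), "B": (5, 0, 0)})
        with pytest.raises(popgen.UndefinedStatistic):
            popgen.weir_cockerham_fst(m, "A", "B")

    def test_permutation_p_large_for_identical_frequencies(self, rng):
        p = rng.uniform(0.3, 0.7, 30)
        g = rng.binomial(2, p, size=(60, 30))
        alleles = np.zeros((60, 30, 2), dtype=int)
        alleles[:, :, 0] = np.where(g >= 1, 1, 2)
        alleles[:, :, 1] = np.where(g == 2, 1, 2)
        inds = pd.DataFrame({"id": [f"i{k}" for k in range(60)],
                             "site": ["A"] * 30 + ["B"] * 30})
        loci = pd.DataFrame({"name": [f"L{j}" for j in range(30)],
                             "kind": "snp", "ploidy": 2})
        m = GenotypeMatrix(inds, loci, alleles)
        assert popgen.permutation_pvalue(m, "A", "B", n_perm=99, seed=1) > 0.05


class TestFdr:
    def test_worked_example(self):
        out = popgen.fdr_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert popgen.fdr_adjust([]).size == 0
        assert np.allclose(popgen.fdr_adjust([1.0, 1.0]), 1.0)
        assert popgen.fdr_adjust([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_matches_reference_stepup(self, pvals):
        """BH equals the hand-coded step-up with monotonicity enforcement."""
        p = np.asarray(pvals)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        assert np.allclose(popgen.fdr_adjust(p), adj, atol=1e-12)


class TestDiversityAndLd:
    @pytest.mark.parametrize("freqs,expect", [
        ([0.5, 0.5], 2.0),
        ([1.0], 1.0),
        ([0.9, 0.1], 1 / 0.82),
    ])
    def test_effective_num_alleles(self, freqs, expect):
        assert popgen.effective_num_alleles(freqs) == pytest.approx(expect, abs=1e-4)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            popgen.effective_num_alleles([0.5, 0.4])

    def _panel_matrix(self, rng, dup=False):
        p_n = np.linspace(0.95, 0.55, 8)
        p_s = 1 - p_n
        n = 40
        g = np.zeros((n, 8), dtype=int)
        for j in range(8):
            g[:20, j] = rng.binomial(2, p_n[j], 20)
            g[20:, j] = rng.binomial(2, p_s[j], 20)
        if dup:
            g[:, 7] = g[:, 6]  # duplicate locus, r^2 = 1
        alleles = np.zeros((n, 8, 2), dtype=int)
        alleles[:, :, 0] = np.where(g >= 1, 1, 2)
        alleles[:, :, 1] = np.where(g == 2, 1, 2)
        inds = pd.DataFrame({"id": [f"i{k}" for k in range(n)],
                             "site": ["N"] * 20 + ["S"] * 20})
        loci = pd.DataFrame({"name": [f"L{j}" for j in range(8)],
                             "kind": "snp", "ploidy": 2})
        return GenotypeMatrix(inds, loci, alleles)

    def test_duplicate_locus_not_both_retained(self, rng):
        m = self._panel_matrix(rng, dup=True)
        assert popgen.ld_r2(m, "L6", "L7") == pytest.approx(1.0)
        panel = popgen.select_informative_panel(m, ["N"], ["S"], 7, r2_max=0.95)
        assert not ({"L6", "L7"} <= set(panel))

    def test_selection_matches_bruteforce_greedy(self, rng):
        m = self._panel_matrix(rng)
        got = popgen.select_informative_panel(m, ["N"], ["S"], 5, r2_max=0.3)
        # independent greedy: rank by per-locus two-group theta, walk down
        fst = popgen._per_locus_group_fst(m, ["N"], ["S"])
        order = sorted(range(8), key=lambda j: -fst[j])
        names = list(m.loci["name"])
        keep = []
        for j in order:
            if all(popgen.ld_r2(m, names[j], k) <= 0.3 for k in keep):
                keep.append(names[j])
            if len(keep) == 5:
                break
        assert got == keep

    def test_infeasible_k_names_maximum(self, rng):
        m = self._panel_matrix(rng, dup=True)
        with pytest.raises(ValueError, match="achievable maximum"):
            popgen.select_informative_panel(m, ["N"], ["S"], 8, r2_max=0.5)


class TestTrees:
    def test_chord_distance_zero_for_identical_profiles(self):
        f = [np.array([0.3, 0.7]), np.array([1.0, 0.0])]
        assert popgen.chord_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_nj_recovers_additive_four_taxon_metric(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive path-length matrix
        dist = {
            ("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
            ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9,
        }
        taxa = ["A", "B", "C", "D"]
        D = pd.DataFrame(0.0, index=taxa, columns=taxa)
        for (a, b), d in dist.items():
            D.loc[a, b] = D.loc[b, a] = d
        import io

        import skbio
        tree = skbio.TreeNode.read(io.StringIO(popgen.neighbor_joining(D)))
        for (a, b), d in dist.items():
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(d, abs=1e-9)

    def test_three_taxon_closed_form(self):
        D = pd.DataFrame([[0, 5, 9], [5, 0, 10], [9, 10, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        import io

        import skbio
        tree = skbio.TreeNode.read(io.StringIO(popgen.neighbor_joining(D)))
        # closed form: d(A) = (dAB + dAC - dBC)/2 etc.
        assert tree.find("A").distance(tree.find("B")) == pytest.approx(5, abs=1e-9)
        assert tree.find("A").distance(tree.find("C")) == pytest.approx(9, abs=1e-9)
        assert tree.find("B").distance(tree.find("C")) == pytest.approx(10, abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            popgen.neighbor_joining(D)

    def test_bootstrap_supports_true_split(self, rng):
        freqs = sim.simulate_parental_frequencies(30, 0.6, seed=3)
        rows, ids, sites = [], [], []
        for site, cls in (("N1", "pureN"), ("N2", "pureN"), ("S1", "pureS"), ("S2", "pureS")):
            for i in range(10):
                rows.append(sim.simulate_genotype(cls, freqs, rng))
                ids.append(f"{site}_{i}")
                sites.append(site)
        inds = pd.DataFrame({"id": ids, "site": sites})
        loci = pd.DataFrame({"name": freqs.loci, "kind": "snp", "ploidy": 2})
        m = GenotypeMatrix(inds, loci, np.stack(rows))
        _, support = popgen.bootstrap_tree(m, n_boot=30, seed=1)
        assert support  # the single internal split N|S
        assert max(support.values()) > 0.9


class TestErrorRate:
    def test_identical_replicates_zero(self, diag_panel, rng):
        g = sim.simulate_genotype("F2", diag_panel, rng)
        assert popgen.genotype_error_rate([(g, g.copy())]) == 0.0

    def test_single_allele_mismatch_over_96_loci(self):
        a = np.ones((96, 2), dtype=int)
        b = a.copy()
        b[0, 1] = 2
        assert popgen.genotype_error_rate([(a, b)]) == pytest.approx(1 / 192)
        assert popgen.genotype_error_rate([(a, b)], per="reaction") == pytest.approx(1 / 96)

    def test_injected_error_rate_recovered(self, rng):
        """0.16% allele flips over >= 10,000 copies land within 3 SE."""
        rate = 0.0016
        n_pairs, L = 60, 96
        pairs = []
        for _ in range(n_pairs):
            a = rng.integers(1, 3, size=(L, 2))
            b = a.copy()
            flips = rng.random((L, 2)) < rate
            b[flips] = 3 - b[flips]
            pairs.append((a, b))
        est = popgen.genotype_error_rate(pairs)
        n_copies = n_pairs * L * 2
        se = np.sqrt(rate * (1 - rate) / n_copies)
        assert abs(est - rate) <= 3 * se

    def test_missing_loci_excluded_and_empty_undefined(self):
        a = np.array([[1, 1], [0, 0]])
        b = np.array([[1, 1], [2, 2]])
        assert popgen.genotype_error_rate([(a, b)]) == 0.0
        with pytest.raises(popgen.UndefinedStatistic):
            popgen.genotype_error_rate([(np.zeros((3, 2), dtype=int),) * 2])
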