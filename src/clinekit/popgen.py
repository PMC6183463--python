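"""Classical population-genetic statistics.

Weir & Cockerham (1984) variance-component F_ST (multi-locus ratio of
sums), permutation tests, Benjamini–Hochberg FDR, effective allele counts,
a composite-genotype LD screen for panel selection, Cavalli-Sforza &
Edwards chord distances with neighbour-joining and locus bootstrap, and
replicate-based genotype error rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from clinekit.gio import GenotypeMatrix


class UndefinedStatistic(ValueError):
    pass


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _site_allele_data(matrix: GenotypeMatrix, site: str):
    """Per locus: dict allele->freq, sample size n, observed het per allele."""
    rows = np.flatnonzero((matrix.individuals["site"] == site).to_numpy())
    if len(rows) == 0:
        raise UndefinedStatistic(f"no individuals at site {site!r}")
    out = []
    for j in range(matrix.n_loci):
        ploidy = int(matrix.loci["ploidy"].iloc[j])
        a = matrix.alleles[rows, j, :ploidy]
        typed = np.all(a != 0, axis=1)
        a = a[typed]
        n = len(a)
        if n == 0:
            out.append(None)
            continue
        alleles, counts = np.unique(a, return_counts=True)
        freqs = dict(zip(alleles.tolist(), (counts / (ploidy * n)).tolist()))
        het = {}
        if ploidy == 2:
            is_het = a[:, 0] != a[:, 1]
            for al in alleles:
                het[int(al)] = float(np.mean(is_het & np.any(a == al, axis=1)))
        out.append({"freqs": freqs, "n": n, "het": het, "ploidy": ploidy})
    return out


def weir_cockerham_fst(matrix: GenotypeMatrix, site_a: str, site_b: str) -> float:
    """Two-population multi-locus Weir–Cockerham theta (ratio of sums).

    Variance components a (among populations), b (among individuals
    within populations) and c (within individuals) are accumulated per
    allele per locus; monomorphic shared loci contribute nothing. The
    unconstrained estimator may be slightly negative.
    """
    da = _site_allele_data(matrix, site_a)
    db = _site_allele_data(matrix, site_b)
    num = 0.0
    den = 0.0
    any_shared = False
    r = 2
    for la, lb in zip(da, db):
        if la is None or lb is None or la["ploidy"] != 2 or lb["ploidy"] != 2:
            continue
        if la["n"] < 2 or lb["n"] < 2:
            continue
        any_shared = True
        alleles = set(la["freqs"]) | set(lb["freqs"])
        if len(alleles) < 2:
            continue  # monomorphic across both sites
        n1, n2 = la["n"], lb["n"]
        n_bar = (n1 + n2) / r
        nc = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        for al in alleles:
            p1 = la["freqs"].get(al, 0.0)
            p2 = lb["freqs"].get(al, 0.0)
            h1 = la["het"].get(al, 0.0)
            h2 = lb["het"].get(al, 0.0)
            p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
            h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
            a = (n_bar / nc) * (
                s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            num += a
            den += a + b + c
    if not any_shared or den == 0:
        raise UndefinedStatistic(
            f"no shared polymorphic diploid loci between {site_a!r} and {site_b!r}"
        )
    return float(num / den)


def permutation_pvalue(matrix: GenotypeMatrix, site_a: str, site_b: str,
                       n_perm: int = 999, seed: int | None = None) -> float:
    """Permutation p-value for F_ST > 0: individuals are shuffled between
    the two sites and theta recomputed; p = (1 + #perm >= obs)/(1 + n_perm)."""
    obs = weir_cockerham_fst(matrix, site_a, site_b)
    sub = matrix.subset_sites([site_a, site_b])
    rng = np.random.default_rng(seed)
    labels = sub.individuals["site"].to_numpy().copy()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        shuffled = GenotypeMatrix(
            sub.individuals.assign(site=perm), sub.loci, sub.alleles
        )
        try:
            if weir_cockerham_fst(shuffled, site_a, site_b) >= obs:
                count += 1
        except UndefinedStatistic:
            count += 1
    return (1 + count) / (1 + n_perm)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_fst_table(matrix: GenotypeMatrix, n_perm: int = 199,
                       seed: int | None = None) -> pd.DataFrame:
    """Long-format table (site_a, site_b, fst, p, p_fdr) over all site pairs."""
    sites = list(pd.unique(matrix.individuals["site"]))
    rng = np.random.default_rng(seed)
    rows = []
    for i, sa in enumerate(sites):
        for sb in sites[i + 1:]:
            fst = weir_cockerham_fst(matrix, sa, sb)
            p = permutation_pvalue(matrix, sa, sb, n_perm=n_perm,
                                   seed=int(rng.integers(2**31 - 1)))
            rows.append({"site_a": sa, "site_b": sb, "fst": fst, "p": p})
    df = pd.DataFrame(rows)
    df["p_fdr"] = fdr_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def effective_num_alleles(freqs) -> float:
    """A_e = 1 / sum(p_i^2); 1 for monomorphic loci."""
    p = np.asarray(freqs, dtype=float)
    if abs(p.sum() - 1) > 1e-6:
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 / np.sum(p**2))


# ---------------------------------------------------------------------------
# LD screen and panel selection
# ---------------------------------------------------------------------------

def ld_r2(matrix: GenotypeMatrix, locus_a: str, locus_b: str) -> float:
    """Composite genotypic r^2: squared Pearson correlation of reference
    allele counts over individuals typed at both loci (no phase assumed)."""
    names = list(matrix.loci["name"])
    ja, jb = names.index(locus_a), names.index(locus_b)
    g = matrix.ref_counts()
    both = ~np.isnan(g[:, ja]) & ~np.isnan(g[:, jb])
    ga, gb = g[both, ja], g[both, jb]
    if len(ga) < 3 or np.std(ga) == 0 or np.std(gb) == 0:
        return 0.0
    return float(np.corrcoef(ga, gb)[0, 1] ** 2)


def _per_locus_group_fst(matrix: GenotypeMatrix, north_sites, south_sites) -> np.ndarray:
    """Per-locus two-group W-C theta (groups pooled as populations)."""
    grouped = matrix.individuals["site"].map(
        lambda s: "N" if s in set(north_sites) else ("S" if s in set(south_sites) else None)
    )
    keep = grouped.notna().to_numpy()
    sub = GenotypeMatrix(matrix.individuals[keep].assign(site=grouped[keep]).reset_index(drop=True),
                         matrix.loci, matrix.alleles[keep])
    out = np.full(matrix.n_loci, np.nan)
    for j in range(matrix.n_loci):
        one = GenotypeMatrix(sub.individuals, sub.loci.iloc[[j]],
                             sub.alleles[:, [j], :])
        try:
            out[j] = weir_cockerham_fst(one, "N", "S")
        except UndefinedStatistic:
            out[j] = np.nan
    return out


def select_informative_panel(matrix: GenotypeMatrix, north_sites, south_sites,
                             k: int, r2_max: float = 0.2) -> list[str]:
    """Greedy top-F_ST panel under an LD ceiling.

    Loci are ranked by between-group per-locus F_ST; walking down the
    ranking, a locus is retained unless its composite r^2 with any already
    retained locus exceeds ``r2_max``. Raises if fewer than ``k`` loci are
    achievable, naming the achievable maximum.
    """
    fst = _per_locus_group_fst(matrix, north_sites, south_sites)
    order = np.argsort(-np.nan_to_num(fst, nan=-np.inf), kind="mergesort")
    names = list(matrix.loci["name"])
    chosen: list[str] = []
    for j in order:
        if np.isnan(fst[j]):
            continue
        if all(ld_r2(matrix, names[j], c) <= r2_max for c in chosen):
            chosen.append(names[j])
        if len(chosen) == k:
            return chosen
    raise ValueError(
        f"cannot select {k} loci under r2_max={r2_max}; achievable maximum is {len(chosen)}"
    )


# ---------------------------------------------------------------------------
# Chord distance, neighbour joining, bootstrap
# ---------------------------------------------------------------------------

def chord_distance(freqs_a, freqs_b) -> float:
    """Cavalli-Sforza & Edwards chord distance between two frequency
    profiles (lists of per-locus allele-frequency vectors):
    ``(2/pi) * sqrt(2 * (1 - mean_l sum_a sqrt(p_a q_a)))``."""
    f = []
    for p, q in zip(freqs_a, freqs_b):
        p, q = np.asarray(p, float), np.asarray(q, float)
        f.append(np.sum(np.sqrt(p * q)))
    fbar = float(np.clip(np.mean(f), 0.0, 1.0))
    return (2 / np.pi) * np.sqrt(2 * (1 - fbar))


def site_frequency_vectors(matrix: GenotypeMatrix) -> dict[str, list[np.ndarray]]:
    """Per site: list of per-locus allele-frequency vectors over the union
    of observed allele codes at each locus."""
    by_site = matrix.allele_counts_by_site()
    sites = list(by_site)
    out: dict[str, list[np.ndarray]] = {s: [] for s in sites}
    for name in matrix.loci["name"]:
        codes = sorted(set().union(*(set(by_site[s][name].index) for s in sites)))
        for s in sites:
            counts = np.array([by_site[s][name].get(c, 0) for c in codes], float)
            tot = counts.sum()
            out[s].append(counts / tot if tot > 0 else np.full(len(codes), np.nan))
    return out


def chord_distance_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    vecs = site_frequency_vectors(matrix)
    sites = list(vecs)
    D = np.zeros((len(sites), len(sites)))
    for i, a in enumerate(sites):
        for j2 in range(i + 1, len(sites)):
            d = chord_distance(vecs[a], vecs[sites[j2]])
            D[i, j2] = D[j2, i] = d
    return pd.DataFrame(D, index=sites, columns=sites)


def neighbor_joining(distance_matrix: pd.DataFrame) -> str:
    """Saitou–Nei neighbour joining; returns Newick with branch lengths."""
    import skbio

    D = distance_matrix.to_numpy(dtype=float)
    if D.shape[0] < 3:
        raise ValueError("neighbour joining requires >= 3 taxa")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
    dm = skbio.DistanceMatrix(D, ids=list(distance_matrix.index))
    tree = skbio.tree.nj(dm)
    return str(tree).strip()


def _bipartitions(newick: str, taxa: frozenset) -> set[frozenset]:
    import io
    import skbio

    tree = skbio.TreeNode.read(io.StringIO(newick))
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            parts.add(min(side, taxa - side, key=lambda s: sorted(s)))
    return parts


def bootstrap_tree(matrix: GenotypeMatrix, n_boot: int = 100,
                   seed: int | None = None) -> tuple[str, dict[frozenset, float]]:
    """NJ tree on chord distances plus locus-bootstrap bipartition support.

    Loci are resampled with replacement ``n_boot`` times; support for each
    internal bipartition of the full-data tree is the fraction of
    bootstrap trees containing it.
    """
    base = neighbor_joining(chord_distance_matrix(matrix))
    taxa = frozenset(pd.unique(matrix.individuals["site"]))
    base_parts = _bipartitions(base, taxa)
    support = {p: 0 for p in base_parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        pick = rng.integers(0, matrix.n_loci, size=matrix.n_loci)
        boot = GenotypeMatrix(
            matrix.individuals,
            matrix.loci.iloc[pick].assign(
                name=[f"b{i}" for i in range(matrix.n_loci)]
            ).reset_index(drop=True),
            matrix.alleles[:, pick, :],
        )
        parts = _bipartitions(neighbor_joining(chord_distance_matrix(boot)), taxa)
        for p in base_parts:
            if p in parts:
                support[p] += 1
    return base, {p: c / n_boot for p, c in support.items()}


# ---------------------------------------------------------------------------
# Genotype error rate
# ---------------------------------------------------------------------------

def genotype_error_rate(replicate_pairs, per: str = "allele") -> float:
    """Replicate-based genotyping error rate.

    ``replicate_pairs`` is an iterable of ``(alleles_a, alleles_b)`` with
    each element an ``(L, 2)`` (or ``(L, 1)``) integer array, 0 = missing.
    ``per='allele'``: mismatched allele copies / allele copies compared
    (genotypes compared as unordered pairs); ``per='reaction'``: loci with
    any mismatch / loci compared. Loci missing in either replicate are
    excluded.
    """
    if per not in ("allele", "reaction"):
        raise ValueError("per must be 'allele' or 'reaction'")
    mism = 0
    total = 0
    for ga, gb in replicate_pairs:
        ga = np.atleast_2d(np.asarray(ga))
        gb = np.atleast_2d(np.asarray(gb))
        for ra, rb in zip(ga, gb):
            ra, rb = ra[ra != 0], rb[rb != 0]
            if len(ra) != len(rb) or len(ra) == 0:
                continue
            a, b = sorted(ra.tolist()), sorted(rb.tolist())
            if per == "allele":
                # unordered-multiset mismatch count
                inter = 0
                bb = list(b)
                for v in a:
                    if v in bb:
                        bb.remove(v)
                        inter += 1
                mism += len(a) - inter
                total += len(a)
            else:
                mism += int(a != b)
                total += 1
    if total == 0:
        raise UndefinedStatistic("no comparable loci between replicates")
    return mism / total
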