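"""Hybrid-class posterior assignment, hybrid index and interlineage
heterozygosity.

Genotype-class model
--------------------
Each diploid genotype class fixes the probabilities of the two gene
copies' lineage origins, phi = (P(N,N), P(N,S), P(S,S)):

===========  ===============
class        phi
===========  ===============
pure north   (1, 0, 0)
pure south   (0, 0, 1)
F1           (0, 1, 0)
F2           (1/4, 1/2, 1/4)
BC north     (1/2, 1/2, 0)
BC south     (0, 1/2, 1/2)
===========  ===============

Per locus, P(genotype | class) marginalizes the ancestry pair with
plug-in parental allele frequencies p_N, p_S (e.g. the heterozygote
probability given origin pair (N,S) is p_N (1-p_S) + (1-p_N) p_S); loci
multiply under linkage equilibrium and missing loci are skipped. The
"recombinant hybrid" super-class aggregates F2 and both backcrosses,
since later-generation hybrids are not reliably separable.

The maximum-likelihood hybrid index h treats each gene copy as northern
with probability h; interlineage heterozygosity is the expected
proportion of strongly differentiated loci carrying one copy of each
lineage origin. Together they place individuals on the triangle plot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from clinekit.gio import GenotypeMatrix
from clinekit.simulate import LineageFrequencies, simulate_genotype

CLASSES = ("pureN", "pureS", "F1", "F2", "BC_N", "BC_S")

CLASS_PHI = {
    "pureN": (1.0, 0.0, 0.0),
    "pureS": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC_N": (0.5, 0.5, 0.0),
    "BC_S": (0.0, 0.5, 0.5),
}

RECOMBINANT = ("F2", "BC_N", "BC_S")


def _genotype_probs_given_pair(p_n: np.ndarray, p_s: np.ndarray) -> np.ndarray:
    """(3 pairs, 3 genotypes, L): P(ref-count g | origin pair) per locus."""
    out = np.empty((3, 3, len(p_n)))
    for i, (pa, pb) in enumerate(((p_n, p_n), (p_n, p_s), (p_s, p_s))):
        out[i, 2] = pa * pb                          # hom reference
        out[i, 1] = pa * (1 - pb) + (1 - pa) * pb    # het
        out[i, 0] = (1 - pa) * (1 - pb)              # hom alternate
    return out


def class_log_likelihood(ref_counts: np.ndarray, class_label: str,
                         freqs: LineageFrequencies) -> float:
    """Log P(genotype row | class) across loci; NaN loci skipped.

    A locus that is impossible under the class (e.g. a heterozygote for a
    pure class at a diagnostic locus) yields -inf.
    """
    phi = np.array(CLASS_PHI[class_label])
    probs = _genotype_probs_given_pair(freqs.p_north, freqs.p_south)
    g = np.asarray(ref_counts, dtype=float)
    typed = ~np.isnan(g)
    gi = g[typed].astype(int)
    pl = np.einsum("p,pgl->gl", phi, probs[:, :, typed])  # (3 genotypes, L typed)
    per_locus = pl[gi, np.arange(typed.sum())]
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(per_locus)))


def class_likelihood(ref_counts, class_label, freqs) -> float:
    return float(np.exp(class_log_likelihood(ref_counts, class_label, freqs)))


def _posterior_matrix(ref: np.ndarray, freqs: LineageFrequencies,
                      priors: dict[str, float]) -> np.ndarray:
    """(n, 6) class posteriors for a ref-count matrix (vectorized)."""
    p_n, p_s = freqs.p_north, freqs.p_south
    probs = _genotype_probs_given_pair(p_n, p_s)      # (3 pairs, 3 geno, L)
    n, L = ref.shape
    logph = np.zeros((n, len(CLASSES)))
    for ci, cls in enumerate(CLASSES):
        phi = np.array(CLASS_PHI[cls])
        pl = np.einsum("p,pgl->gl", phi, probs)       # (3 geno, L)
        with np.errstate(divide="ignore"):
            logpl = np.log(pl)
        g = ref.copy()
        typed = ~np.isnan(g)
        gi = np.nan_to_num(g, nan=0).astype(int)
        vals = logpl[gi, np.arange(L)[None, :]]
        vals = np.where(typed, vals, 0.0)
        logph[:, ci] = vals.sum(axis=1)
    logph += np.log([priors[c] for c in CLASSES])[None, :]
    m = logph.max(axis=1, keepdims=True)
    finite = np.isfinite(m)
    w = np.exp(logph - np.where(finite, m, 0.0))
    w[~np.isfinite(w)] = 0.0
    tot = w.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return w / tot


def assign_classes(matrix: GenotypeMatrix | np.ndarray, freqs: LineageFrequencies,
                   priors: dict[str, float] | None = None,
                   threshold: float = 0.85) -> pd.DataFrame:
    """Posterior class assignment per individual.

    Returns a table with the six class posteriors, the 6-class ``call``
    (argmax if it reaches ``threshold``, else ``unassigned``) and the
    aggregated 3-class ``call3`` (pureN / pureS / hybrid) computed from
    posteriors summed over the four hybrid classes.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if priors is None:
        priors = {c: 1 / len(CLASSES) for c in CLASSES}
    if isinstance(matrix, GenotypeMatrix):
        ref = _freq_oriented_counts(matrix)
        ids = list(matrix.individuals["id"])
        sites = list(matrix.individuals["site"])
    else:
        ref = np.atleast_2d(np.asarray(matrix, dtype=float))
        ids = [f"ind{i}" for i in range(len(ref))]
        sites = [""] * len(ref)
    post = _posterior_matrix(ref, freqs, priors)
    df = pd.DataFrame(post, columns=list(CLASSES))
    df.insert(0, "id", ids)
    df.insert(1, "site", sites)
    best = post.argmax(axis=1)
    best_p = post.max(axis=1)
    df["call"] = [CLASSES[b] if p >= threshold else "unassigned"
                  for b, p in zip(best, best_p)]
    agg = np.stack([post[:, 0], post[:, 1],
                    post[:, 2:].sum(axis=1)], axis=1)
    b3 = agg.argmax(axis=1)
    p3 = agg.max(axis=1)
    names3 = ("pureN", "pureS", "hybrid")
    df["p_pureN"] = agg[:, 0]
    df["p_pureS"] = agg[:, 1]
    df["p_hybrid"] = agg[:, 2]
    df["call3"] = [names3[b] if p >= threshold else "unassigned"
                   for b, p in zip(b3, p3)]
    return df


def simulate_assignment_success(freqs: LineageFrequencies,
                                classes=("pureN", "pureS", "F1", "F2", "BC_N", "BC_S"),
                                n_per_class: int = 200, n_datasets: int = 3,
                                seed: int | None = None, threshold: float = 0.85,
                                level: str = "three") -> pd.DataFrame:
    """Power analysis on simulated hybrids: per-class assignment success.

    Each dataset simulates ``n_per_class`` individuals per class and scores
    the proportion correctly called at ``threshold``; success is judged at
    the aggregated three-class level (``level='three'``: hybrids of any
    generation are correct when called ``hybrid``) or at the six-class
    level. Returns class, mean success and SE across datasets.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    per_class: dict[str, list[float]] = {c: [] for c in classes}
    for _ in range(n_datasets):
        for cls in classes:
            rows = np.stack([
                _ref_counts_row(simulate_genotype(cls, freqs, rng), freqs)
                for _ in range(n_per_class)
            ])
            table = assign_classes(rows, freqs, threshold=threshold)
            if level == "three":
                want = {"pureN": "pureN", "pureS": "pureS"}.get(cls, "hybrid")
                ok = (table["call3"] == want).mean()
            else:
                ok = (table["call"] == cls).mean()
            per_class[cls].append(float(ok))
    rows = []
    for cls in classes:
        vals = np.array(per_class[cls])
        rows.append({"class": cls, "success": vals.mean(),
                     "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0})
    return pd.DataFrame(rows)


def _ref_counts_row(alleles: np.ndarray, freqs: LineageFrequencies) -> np.ndarray:
    """Reference(first)-allele count per locus from a simulated allele row."""
    ploidy = freqs.ploidy
    return (alleles[:, :ploidy] == 1).sum(axis=1).astype(float)


def _freq_oriented_counts(matrix: GenotypeMatrix) -> np.ndarray:
    """Counts of allele code 1 — the allele the lineage frequencies refer
    to. (``GenotypeMatrix.ref_counts`` counts the smallest *observed* code,
    which silently flips polarity at loci where allele 1 was never seen.)"""
    counts = (matrix.alleles == 1).sum(axis=2).astype(float)
    counts[matrix.missing_mask()] = np.nan
    return counts


# ---------------------------------------------------------------------------
# Hybrid index and interlineage heterozygosity
# ---------------------------------------------------------------------------

def _hybrid_index_nll(h: float, g: np.ndarray, p_n: np.ndarray, p_s: np.ndarray) -> float:
    q = h * p_n + (1 - h) * p_s
    q = np.clip(q, 1e-12, 1 - 1e-12)
    ll = np.where(g == 1, np.log(2 * q * (1 - q)),
                  np.where(g == 2, 2 * np.log(q), 2 * np.log(1 - q)))
    return float(-ll.sum())


def hybrid_index_ml(ref_counts, freqs: LineageFrequencies, tol: float = 1e-4) -> float:
    """ML hybrid index: h maximizing the binomial likelihood in which each
    gene copy is of northern origin with probability h. Returns NaN (with
    a warning) when no locus is informative (flat likelihood)."""
    g = np.asarray(ref_counts, dtype=float)
    typed = ~np.isnan(g)
    g = g[typed]
    p_n, p_s = freqs.p_north[typed], freqs.p_south[typed]
    informative = p_n != p_s
    if not informative.any():
        import warnings

        warnings.warn("hybrid index undefined: no informative loci")
        return float("nan")
    res = optimize.minimize_scalar(_hybrid_index_nll, bounds=(0.0, 1.0),
                                   args=(g, p_n, p_s), method="bounded",
                                   options={"xatol": tol / 10})
    # the bounded minimizer can stall a hair inside the boundary
    for edge in (0.0, 1.0):
        if _hybrid_index_nll(edge, g, p_n, p_s) < res.fun:
            return edge
    return float(res.x)


def interlineage_heterozygosity(ref_counts, freqs: LineageFrequencies,
                                delta_min: float = 0.5,
                                h: float | None = None) -> float:
    """Expected proportion of strongly differentiated loci with one
    northern- and one southern-origin copy.

    Restricted to loci with |p_N - p_S| >= ``delta_min``; per qualifying
    locus the two copies' origin posteriors (prior: each copy northern
    w.p. the individual's hybrid index h) give
    P(one copy of each origin). Equals the exact heterozygote count on
    diagnostic loci.
    """
    if not 0 < delta_min <= 1:
        raise ValueError("delta_min must be in (0, 1]")
    g = np.asarray(ref_counts, dtype=float)
    typed = ~np.isnan(g)
    p_n, p_s = freqs.p_north, freqs.p_south
    qual = typed & (np.abs(p_n - p_s) >= delta_min)
    if not qual.any():
        import warnings

        warnings.warn("interlineage heterozygosity undefined: no qualifying loci")
        return float("nan")
    if h is None:
        h = hybrid_index_ml(ref_counts, freqs)
    if np.isnan(h):
        return float("nan")
    g = g[qual]
    p_n, p_s = p_n[qual], p_s[qual]
    # per-copy posterior P(northern origin | allele), copy alleles from genotype
    def p_north_given(allele_is_ref):
        like_n = np.where(allele_is_ref, p_n, 1 - p_n)
        like_s = np.where(allele_is_ref, p_s, 1 - p_s)
        num = h * like_n
        den = num + (1 - h) * like_s
        den = np.where(den == 0, 1.0, den)
        return num / den
    # copy 1 is ref iff g >= 1, copy 2 is ref iff g == 2
    a1 = p_north_given(g >= 1)
    a2 = p_north_given(g == 2)
    inter = a1 * (1 - a2) + (1 - a1) * a2
    return float(inter.mean())


def triangle_table(matrix: GenotypeMatrix, freqs: LineageFrequencies,
                   delta_min: float = 0.5) -> pd.DataFrame:
    """Per-individual hybrid index and interlineage heterozygosity."""
    ref = _freq_oriented_counts(matrix)
    rows = []
    for i in range(matrix.n_individuals):
        h = hybrid_index_ml(ref[i], freqs)
        het = interlineage_heterozygosity(ref[i], freqs, delta_min, h=h)
        rows.append({"id": matrix.individuals["id"].iloc[i],
                     "site": matrix.individuals["site"].iloc[i],
                     "hybrid_index": h, "interlineage_het": het})
    return pd.DataFrame(rows)
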