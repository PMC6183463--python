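"""Two-cluster maximum-likelihood admixture estimation.

Standard admixture likelihood for K = 2: each of an individual's allele
copies derives independently from cluster 1 with probability Q_i, and the
copy's allele is drawn from that cluster's frequency vector at the locus.
Point estimates come from EM (monotone in log-likelihood), run from
multiple seeded starts with the best optimum kept. Label switching is
resolved by anchoring cluster 1 ("northern") to the cluster with the
higher mean membership among a designated reference group (default: the
individuals of the first site).

Multiallelic loci are handled natively (one frequency per observed allele
per cluster); missing copies are skipped in the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clinekit.gio import GenotypeMatrix
from clinekit.popgen import effective_num_alleles


@dataclass
class AdmixtureResult:
    q: pd.Series                 # individual id -> P(northern-cluster ancestry)
    cluster_freqs: pd.DataFrame  # rows (locus, allele), cols cluster1/cluster2
    log_likelihood: float
    log_likelihood_path: np.ndarray
    iterations: int
    converged: bool
    seed: int | None


def _copy_count_matrix(matrix: GenotypeMatrix):
    """(n, A_total) per-individual allele-copy counts, with per-locus
    column blocks; columns labelled (locus, allele code)."""
    blocks = []
    labels = []
    locus_slices = []
    col = 0
    for j, name in enumerate(matrix.loci["name"]):
        ploidy = int(matrix.loci["ploidy"].iloc[j])
        a = matrix.alleles[:, j, :ploidy]
        codes = np.unique(a[a != 0])
        if len(codes) == 0:
            continue
        C = np.stack([(a == c).sum(axis=1) for c in codes], axis=1).astype(float)
        blocks.append(C)
        labels.extend((name, int(c)) for c in codes)
        locus_slices.append(slice(col, col + len(codes)))
        col += len(codes)
    if not blocks:
        raise ValueError("no typed loci")
    return np.hstack(blocks), labels, locus_slices


def _normalize_blocks(F: np.ndarray, locus_slices) -> np.ndarray:
    for sl in locus_slices:
        tot = F[:, sl].sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        F[:, sl] /= tot
    return F


def _log_likelihood(C, Q, F):
    mix = Q[:, None] * F[0][None, :] + (1 - Q)[:, None] * F[1][None, :]
    return float(np.sum(C * np.log(np.clip(mix, 1e-300, None))))


def _em_run(C, locus_slices, Q0, F0, tol, max_iter):
    Q, F = Q0.copy(), F0.copy()
    path = []
    ll_prev = -np.inf
    it = 0
    converged = False
    total_copies = C.sum(axis=1)
    for it in range(1, max_iter + 1):
        w1 = Q[:, None] * F[0][None, :]
        w2 = (1 - Q)[:, None] * F[1][None, :]
        denom = np.clip(w1 + w2, 1e-300, None)
        r = w1 / denom                      # P(copy from cluster 1)
        e1 = C * r
        e2 = C * (1 - r)
        Q = e1.sum(axis=1) / np.clip(total_copies, 1e-12, None)
        Q = np.clip(Q, 1e-9, 1 - 1e-9)
        F = np.vstack([e1.sum(axis=0), e2.sum(axis=0)])
        F = np.clip(F, 1e-9, None)
        F = _normalize_blocks(F, locus_slices)
        ll = _log_likelihood(C, Q, F)
        if ll < ll_prev - 1e-8:
            raise RuntimeError(f"EM log-likelihood decreased at iteration {it}")
        path.append(ll)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    return Q, F, np.array(path), it, converged


def fit_admixture_k2(matrix: GenotypeMatrix, n_starts: int = 8,
                     tol: float = 1e-6, max_iter: int = 2000,
                     seed: int | None = None,
                     reference_group: list[str] | None = None) -> AdmixtureResult:
    """EM point estimate of per-individual admixture proportions at K = 2.

    ``reference_group`` is a list of individual IDs anchoring cluster 1
    (default: all individuals at the first site in the table); after
    fitting, clusters are swapped if needed so the reference group's mean
    Q is >= 0.5, making the output deterministic given the seed.
    """
    if matrix.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    C, labels, locus_slices = _copy_count_matrix(matrix)
    poly = [sl for sl in locus_slices if sl.stop - sl.start > 1]
    if not poly:
        raise ValueError("all loci monomorphic: admixture unidentifiable")
    rng = np.random.default_rng(seed)
    n, A = C.shape
    # overall frequencies as the perturbation baseline
    base = _normalize_blocks(C.sum(axis=0, keepdims=True).astype(float).repeat(2, axis=0),
                             locus_slices)
    best = None
    for _ in range(n_starts):
        Q0 = rng.uniform(0.05, 0.95, size=n)
        noise = rng.uniform(-0.2, 0.2, size=(2, A))
        F0 = _normalize_blocks(np.clip(base + noise, 1e-3, None), locus_slices)
        out = _em_run(C, locus_slices, Q0, F0, tol, max_iter)
        if best is None or out[2][-1] > best[2][-1]:
            best = out
    Q, F, path, iters, converged = best
    ids = matrix.individuals["id"]
    if reference_group is None:
        first_site = matrix.individuals["site"].iloc[0]
        ref_mask = (matrix.individuals["site"] == first_site).to_numpy()
    else:
        ref_mask = matrix.individuals["id"].isin(reference_group).to_numpy()
    if Q[ref_mask].mean() < 0.5:
        Q = 1 - Q
        F = F[::-1]
    freq_df = pd.DataFrame(
        {"cluster1": F[0], "cluster2": F[1]},
        index=pd.MultiIndex.from_tuples(labels, names=["locus", "allele"]),
    )
    return AdmixtureResult(pd.Series(Q, index=ids, name="Q"), freq_df,
                           float(path[-1]), path, iters, converged, seed)


def per_individual_log_likelihood(matrix: GenotypeMatrix, q: np.ndarray,
                                  F: np.ndarray | None = None,
                                  cluster_freqs: pd.DataFrame | None = None) -> np.ndarray:
    """Log-likelihood of each individual at given Q and cluster frequencies
    (either as the internal (2, A) array or the result DataFrame)."""
    C, labels, _ = _copy_count_matrix(matrix)
    if F is None:
        F = cluster_freqs.loc[labels].to_numpy().T
    mix = np.asarray(q)[:, None] * F[0][None, :] + (1 - np.asarray(q))[:, None] * F[1][None, :]
    return np.sum(C * np.log(np.clip(mix, 1e-300, None)), axis=1)


def mean_site_q(result: AdmixtureResult, matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site mean Q with sample size and mean effective allele count.

    The mean effective allele count (A_e averaged over loci, from the
    site's own allele frequencies) is the conventional cline-model weight
    for admixture-proportion profiles.
    """
    inds = matrix.individuals.set_index("id")
    q = result.q
    rows = []
    by_site = matrix.allele_counts_by_site()
    for site in pd.unique(matrix.individuals["site"]):
        members = inds.index[inds["site"] == site]
        qs = q.loc[q.index.intersection(members)]
        if len(qs) == 0:
            import warnings

            warnings.warn(f"site {site!r} has no individuals with Q estimates; omitted")
            continue
        aes = []
        for name, counts in by_site[site].items():
            tot = counts.sum()
            if tot > 0:
                aes.append(effective_num_alleles(counts.to_numpy() / tot))
        rows.append({"site": site, "mean_q": float(qs.mean()), "n": len(qs),
                     "mean_ae": float(np.mean(aes)) if aes else np.nan})
    return pd.DataFrame(rows)
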