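"""Population structure of the simulated transect.

QC-filters the genotypes, measures end-to-end divergence (Weir–Cockerham
F_ST with a permutation test), builds the chord-distance neighbour-joining
tree of all sites, and estimates per-individual admixture proportions by
K=2 EM — the per-site mean Q that feeds the cline models.

Requires analysis/01_simulate_dataset.py to have run.
"""

from pathlib import Path

import pandas as pd

from clinekit import admixture as adm
from clinekit import gio, popgen

SEED = 43
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main():
    matrix = gio.read_wide_csv(DATA / "snp_transect.csv")
    matrix, dropped = gio.apply_quality_filter(matrix, 9)
    print(f"QC: dropped {len(dropped)} individuals (>9 failed loci)")

    sites = pd.read_csv(DATA / "sites.csv")
    south, north = sites["code"].iloc[0], sites["code"].iloc[-1]
    fst = popgen.weir_cockerham_fst(matrix, south, north)
    p = popgen.permutation_pvalue(matrix, south, north, n_perm=199, seed=SEED)
    print(f"end-to-end F_ST {south} vs {north}: {fst:.3f} (perm p = {p:.3f})")
    pd.DataFrame([{"site_a": south, "site_b": north, "fst": fst, "p": p,
                   "p_fdr": popgen.fdr_adjust([p])[0]}]).to_csv(
        RESULTS / "02_fst.csv", index=False)

    tree, support = popgen.bootstrap_tree(matrix, n_boot=100, seed=SEED)
    (RESULTS / "02_nj_tree.nwk").write_text(tree + "\n")
    strong = sum(1 for s in support.values() if s >= 0.7)
    print(f"NJ tree: {len(support)} internal splits, {strong} with >= 70% bootstrap")

    north_ids = list(matrix.individuals.loc[matrix.individuals["site"]
                                            == north, "id"])
    res = adm.fit_admixture_k2(matrix, n_starts=4, seed=SEED,
                               reference_group=north_ids)
    mean_q = adm.mean_site_q(res, matrix).merge(
        sites[["code", "distance_km"]], left_on="site", right_on="code")
    mean_q.drop(columns="code").to_csv(RESULTS / "02_site_mean_q.csv", index=False)
    ends = mean_q.sort_values("distance_km")["mean_q"]
    print(f"admixture: mean Q runs {ends.iloc[0]:.3f} (south) -> "
          f"{ends.iloc[-1]:.3f} (north); logL {res.log_likelihood:.1f}, "
          f"{res.iterations} EM iterations")


if __name__ == "__main__":
    main()
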