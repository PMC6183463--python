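"""End-to-end orchestration of the analysis stages.

Stages: simulate (or ingest) -> qc -> stats -> distance -> admixture ->
hybrids -> cline -> report. Each stage reads only the written artifacts
of earlier stages (the pipeline is restartable at any stage) and writes
its outputs plus a ``manifest.json`` (config echo, seeds, input
checksums, package version) under ``outdir/<stage>/``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import clinekit
from clinekit import gio, simulate as sim, popgen, admixture as adm, hybrids, coastal, clines

STAGES = ("simulate", "qc", "stats", "distance", "admixture", "hybrids", "cline", "report")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "n_loci": 48,
        "divergence": 0.344,
        "sites": 15,
        "span_km": 2400.0,
        "n_per_site": 16,
        "centre_km": 1300.0,
        "width_km": 600.0,
        "dropout": 0.0,
    },
    "qc": {"max_failed_loci": 9},
    "stats": {"n_perm": 99},
    "distance": {"use_simulated": True},
    "admixture": {"n_starts": 4, "tol": 1e-6, "max_iter": 2000},
    "hybrids": {"threshold": 0.85, "delta_min": 0.5},
    "cline": {"n_starts": 8},
    "report": {},
}


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and key in cfg:
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and key in cfg:
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(stage_dir: Path, config: dict, inputs: list[Path], seed) -> None:
    manifest = {
        "version": clinekit.__version__,
        "seed": seed,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "outputs": sorted(p.name for p in stage_dir.iterdir() if p.name != "manifest.json"),
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_dir(outdir, stage) -> Path:
    d = Path(outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def stage_simulate(config, outdir):
    d = _stage_dir(outdir, "simulate")
    c = config["simulate"]
    seed = int(config["seed"])
    freqs = sim.simulate_parental_frequencies(c["n_loci"], c["divergence"], seed=seed)
    cline = sim.TrueCline(c["centre_km"], c["width_km"])
    ds = sim.simulate_transect(int(c["sites"]), cline, int(c["n_per_site"]), freqs,
                               seed=seed + 1, span=c["span_km"], dropout=c["dropout"])
    gio.write_genepop(ds.matrix, d / "genotypes.gen")
    gio.write_wide_csv(ds.matrix, d / "genotypes.csv")
    ds.sites.to_csv(d / "sites.csv", index=False)
    ds.truth.to_csv(d / "truth.csv", index=False)
    pd.DataFrame({"locus": freqs.loci,
                  "p_north": freqs.p_north,
                  "p_south": freqs.p_south}).to_csv(d / "lineage_freqs.csv", index=False)
    _write_manifest(d, config, [], seed)


def stage_qc(config, outdir):
    d = _stage_dir(outdir, "qc")
    src = Path(outdir) / "simulate"
    matrix = gio.read_wide_csv(src / "genotypes.csv")
    filtered, dropped = gio.apply_quality_filter(matrix, config["qc"]["max_failed_loci"])
    gio.write_wide_csv(filtered, d / "genotypes.csv")
    pd.DataFrame({"dropped_id": dropped}).to_csv(d / "dropped.csv", index=False)
    _write_manifest(d, config, [src / "genotypes.csv"], config["seed"])


def stage_stats(config, outdir):
    d = _stage_dir(outdir, "stats")
    src = Path(outdir) / "qc" / "genotypes.csv"
    matrix = gio.read_wide_csv(src)
    # F_ST between the transect end sites (full pairwise is quadratic; ends
    # summarize the panel divergence)
    sites = list(pd.unique(matrix.individuals["site"]))
    fst = popgen.weir_cockerham_fst(matrix, sites[0], sites[-1])
    p = popgen.permutation_pvalue(matrix, sites[0], sites[-1],
                                  n_perm=config["stats"]["n_perm"], seed=config["seed"])
    pd.DataFrame([{"site_a": sites[0], "site_b": sites[-1], "fst": fst, "p": p,
                   "p_fdr": popgen.fdr_adjust([p])[0]}]).to_csv(d / "fst.csv", index=False)
    tree, support = popgen.bootstrap_tree(matrix, n_boot=25, seed=config["seed"])
    (d / "nj_tree.nwk").write_text(tree + "\n")
    pd.DataFrame([{"bipartition": "|".join(sorted(p)), "support": s}
                  for p, s in support.items()]).to_csv(d / "nj_support.csv", index=False)
    _write_manifest(d, config, [src], config["seed"])


def stage_distance(config, outdir):
    d = _stage_dir(outdir, "distance")
    src = Path(outdir) / "simulate" / "sites.csv"
    sites = pd.read_csv(src)
    # simulated transects carry authoritative distances
    sites[["code", "distance_km"]].to_csv(d / "distances.csv", index=False)
    _write_manifest(d, config, [src], config["seed"])


def stage_admixture(config, outdir):
    d = _stage_dir(outdir, "admixture")
    src = Path(outdir) / "qc" / "genotypes.csv"
    matrix = gio.read_wide_csv(src)
    c = config["admixture"]
    # anchor cluster 1 (northern) on the northernmost site of the transect
    dist = pd.read_csv(Path(outdir) / "distance" / "distances.csv")
    north_site = dist.loc[dist["distance_km"].idxmax(), "code"]
    ref_ids = list(matrix.individuals.loc[matrix.individuals["site"] == north_site, "id"])
    res = adm.fit_admixture_k2(matrix, n_starts=c["n_starts"], tol=c["tol"],
                               max_iter=c["max_iter"], seed=config["seed"],
                               reference_group=ref_ids or None)
    q = res.q.reset_index()
    q.columns = ["id", "Q"]
    q = q.merge(matrix.individuals[["id", "site"]], on="id")
    q.to_csv(d / "q_values.csv", index=False)
    res.cluster_freqs.to_csv(d / "cluster_freqs.csv")
    adm.mean_site_q(res, matrix).to_csv(d / "site_mean_q.csv", index=False)
    _write_manifest(d, config, [src], config["seed"])


def stage_hybrids(config, outdir):
    d = _stage_dir(outdir, "hybrids")
    src = Path(outdir) / "qc" / "genotypes.csv"
    matrix = gio.read_wide_csv(src)
    fr = pd.read_csv(Path(outdir) / "simulate" / "lineage_freqs.csv")
    freqs = sim.LineageFrequencies(
        [np.array([p, 1 - p]) for p in fr["p_north"]],
        [np.array([p, 1 - p]) for p in fr["p_south"]],
        list(fr["locus"]),
    )
    c = config["hybrids"]
    table = hybrids.assign_classes(matrix, freqs, threshold=c["threshold"])
    table.to_csv(d / "assignments.csv", index=False)
    hybrids.triangle_table(matrix, freqs, delta_min=c["delta_min"]).to_csv(
        d / "triangle.csv", index=False)
    _write_manifest(d, config, [src], config["seed"])


def stage_cline(config, outdir):
    d = _stage_dir(outdir, "cline")
    q = pd.read_csv(Path(outdir) / "admixture" / "site_mean_q.csv")
    dist = pd.read_csv(Path(outdir) / "distance" / "distances.csv")
    merged = q.merge(dist, left_on="site", right_on="code")
    profile = clines.SiteFrequencyProfile(
        merged["distance_km"].to_numpy(),
        1 - merged["mean_q"].to_numpy(),   # southern-ancestry frequency
        np.maximum(merged["mean_ae"].to_numpy() * merged["n"].to_numpy(), 1.0),
        marker="Q", year=None,
    )
    best, table = clines.model_selection(profile, n_starts=config["cline"]["n_starts"],
                                         seed=config["seed"])
    table.to_csv(d / "model_table.csv", index=False)
    row = {
        "marker": "Q", "model": str(best.spec) if best.spec else "null",
        "AICc": best.aicc,
        "centre_ml": best.centre, "centre_2ll_low": best.centre_limits[0] if best.centre_limits else np.nan,
        "centre_2ll_high": best.centre_limits[1] if best.centre_limits else np.nan,
        "width_ml": best.width, "width_2ll_low": best.width_limits[0] if best.width_limits else np.nan,
        "width_2ll_high": best.width_limits[1] if best.width_limits else np.nan,
    }
    pd.DataFrame([row]).to_csv(d / "cline_fit.csv", index=False)
    _write_manifest(d, config, [], config["seed"])


CLINE_TABLE_SCHEMA = ["marker", "model", "AICc", "centre_ml", "centre_2ll_low",
                      "centre_2ll_high", "width_ml", "width_2ll_low", "width_2ll_high"]


def stage_report(config, outdir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = _stage_dir(outdir, "report")
    notes = []
    # cline curve
    fit = pd.read_csv(Path(outdir) / "cline" / "cline_fit.csv")
    fit.to_csv(d / "cline_table.csv", index=False)
    q = pd.read_csv(Path(outdir) / "admixture" / "site_mean_q.csv")
    dist = pd.read_csv(Path(outdir) / "distance" / "distances.csv")
    merged = q.merge(dist, left_on="site", right_on="code").sort_values("distance_km")
    figpath = d / "cline.png"
    figure, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(merged["distance_km"], 1 - merged["mean_q"], c="k", label="sites")
    row = fit.iloc[0]
    if not np.isnan(row["centre_ml"]):
        xs = np.linspace(merged["distance_km"].min(), merged["distance_km"].max(), 300)
        params = clines.ClineParams(row["centre_ml"], row["width_ml"])
        ax.plot(xs, clines.cline_value(params, xs), "r-", label="ML cline")
        ax.axvspan(row["centre_2ll_low"], row["centre_2ll_high"], alpha=0.2)
    ax.set_xlabel("distance from southern terminus (km)")
    ax.set_ylabel("southern ancestry frequency")
    ax.legend()
    figure.savefig(figpath, dpi=100)
    plt.close(figure)
    # stacked-Q bars
    qv = pd.read_csv(Path(outdir) / "admixture" / "q_values.csv")
    figure, ax = plt.subplots(figsize=(8, 2.5))
    qv = qv.merge(dist, left_on="site", right_on="code").sort_values(["distance_km", "Q"])
    ax.bar(range(len(qv)), qv["Q"], width=1, color="tab:blue")
    ax.bar(range(len(qv)), 1 - qv["Q"], bottom=qv["Q"], width=1, color="tab:red")
    ax.set_ylim(0, 1)
    ax.set_ylabel("Q")
    figure.savefig(d / "structure_bars.png", dpi=100)
    plt.close(figure)
    # triangle plot
    tri = pd.read_csv(Path(outdir) / "hybrids" / "triangle.csv")
    assigns = pd.read_csv(Path(outdir) / "hybrids" / "assignments.csv")
    n_hyb = int((assigns["call3"] == "hybrid").sum())
    if n_hyb == 0:
        notes.append("no hybrids detected")
    figure, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(tri["hybrid_index"], tri["interlineage_het"], s=8)
    ax.set_xlabel("hybrid index h")
    ax.set_ylabel("interlineage heterozygosity")
    figure.savefig(d / "triangle.png", dpi=100)
    plt.close(figure)
    (d / "notes.txt").write_text("\n".join(notes) + "\n")
    summary = {"n_individuals": int(len(qv)), "n_hybrids": n_hyb,
               "cline_centre_km": float(row["centre_ml"]),
               "cline_width_km": float(row["width_ml"])}
    (d / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_manifest(d, config, [], config["seed"])


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "stats": stage_stats,
    "distance": stage_distance,
    "admixture": stage_admixture,
    "hybrids": stage_hybrids,
    "cline": stage_cline,
    "report": stage_report,
}


def run_pipeline(config: dict, outdir, stages=None) -> Path:
    """Run the requested stages in order; halts on the failing stage with
    earlier artifacts preserved. Identical config + seed reproduce
    identical outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in stages or STAGES:
        if stage not in STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            raise StageError(stage, exc) from exc
    return outdir
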