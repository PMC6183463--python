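"""Synthetic two-lineage genotype data.

Generates datasets with the statistical structure the downstream analyses
assume: two parental lineages at a tunable divergence, hybrid classes
(pure, F1, F2, backcross, F3), latitudinal transects with sigmoid ancestry
clines, and temporal snapshots with a linearly moving cline centre.

Parental allele frequencies come from a Balding–Nichols-style model: an
ancestral frequency is drawn per locus and each lineage's frequency is a
Beta deviate around it with concentration ``(1 - F)/F``; ``F`` is
calibrated by bisection so the realized mean per-locus F_ST between the
two frequency vectors hits the requested divergence. Loci are unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clinekit.gio import GenotypeMatrix

HYBRID_CLASSES = ("pureN", "pureS", "F1", "F2", "BC_N", "BC_S", "F3")

# ancestry-pair probabilities P(N,N), P(N,S), P(S,S) per class, one locus
CLASS_ANCESTRY = {
    "pureN": (1.0, 0.0, 0.0),
    "pureS": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC_N": (0.5, 0.5, 0.0),
    "BC_S": (0.0, 0.5, 0.5),
    # With free recombination an F2 gamete is N or S with probability 1/2
    # independently per locus, so an F2 x F2 union has the F2 distribution.
    "F3": (0.25, 0.5, 0.25),
}


@dataclass
class LineageFrequencies:
    """Per-locus allele frequencies in the northern and southern lineage.

    ``freqs_north[j]`` / ``freqs_south[j]`` are frequency vectors over the
    alleles of locus j (length 2 for SNPs and mtDNA haplotypes). For
    biallelic markers :attr:`p_north` / :attr:`p_south` expose the
    frequency of the reference (first) allele.
    """

    freqs_north: list[np.ndarray]
    freqs_south: list[np.ndarray]
    loci: list[str]
    kind: str = "snp"  # snp | microsat | mtdna

    def __post_init__(self) -> None:
        if not (len(self.freqs_north) == len(self.freqs_south) == len(self.loci)):
            raise ValueError("frequency vectors and locus labels differ in length")
        for pn, ps in zip(self.freqs_north, self.freqs_south):
            for v in (pn, ps):
                if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                    raise ValueError("allele frequencies outside [0, 1]")
                if abs(v.sum() - 1) > 1e-6:
                    raise ValueError("allele frequencies must sum to 1")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ploidy(self) -> int:
        return 1 if self.kind == "mtdna" else 2

    @property
    def p_north(self) -> np.ndarray:
        return np.array([v[0] for v in self.freqs_north])

    @property
    def p_south(self) -> np.ndarray:
        return np.array([v[0] for v in self.freqs_south])

    def per_locus_divergence(self) -> np.ndarray:
        """Parametric per-locus F_ST between the two frequency vectors."""
        num, den = _fst_components(self.freqs_north, self.freqs_south)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, 0.0)

    def mean_divergence(self) -> float:
        """Parametric multi-locus (ratio of sums) F_ST."""
        num, den = _fst_components(self.freqs_north, self.freqs_south)
        return float(num.sum() / den.sum())

    def mean_per_locus_divergence(self) -> float:
        """Unweighted mean of per-locus F_ST (the panel summary that
        divergence targets are calibrated against)."""
        return float(self.per_locus_divergence().mean())


@dataclass
class TrueCline:
    """Generating sigmoid ancestry cline along the transect.

    ``orientation='increasing'`` means northern ancestry increases with
    distance from the (southern) transect origin.
    """

    centre: float
    width: float
    orientation: str = "increasing"
    p_min: float = 0.0
    p_max: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if not (0 <= self.p_min < self.p_max <= 1):
            raise ValueError("require 0 <= p_min < p_max <= 1")

    def northern_ancestry(self, x) -> np.ndarray:
        """Expected northern-ancestry proportion at transect distance x."""
        x = np.asarray(x, dtype=float)
        s = (1 + np.tanh(2 * (x - self.centre) / self.width)) / 2
        if self.orientation == "decreasing":
            s = 1 - s
        return self.p_min + (self.p_max - self.p_min) * s


@dataclass
class SimulatedDataset:
    matrix: GenotypeMatrix
    sites: pd.DataFrame          # code, distance_km, lat, lon, year, stage, n
    truth: pd.DataFrame          # id, site, true_class, true_q
    freqs: LineageFrequencies
    true_cline: TrueCline | None
    seed: int
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Parental frequencies
# ---------------------------------------------------------------------------

def _fst_components(freqs_a, freqs_b) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (numerator, denominator) of the parametric two-population
    F_ST: 1 - Hw/Hb with Hw the mean within-lineage heterozygosity and Hb
    the between-lineage heterozygosity (equal weights, infinite samples)."""
    num = np.empty(len(freqs_a))
    den = np.empty(len(freqs_a))
    for j, (p, q) in enumerate(zip(freqs_a, freqs_b)):
        hb = 1 - float(np.dot(p, q))
        hw = 1 - (float(np.dot(p, p)) + float(np.dot(q, q))) / 2
        num[j] = hb - hw
        den[j] = hb
    return num, den


def _draw_frequencies(n_loci: int, f: float, n_alleles: int, rng: np.random.Generator):
    """One Balding–Nichols draw of paired lineage frequencies."""
    conc = (1 - f) / f
    fn, fs = [], []
    for _ in range(n_loci):
        if n_alleles == 2:
            anc = rng.uniform(0.05, 0.95)
            base = np.array([anc, 1 - anc])
        else:
            base = rng.dirichlet(np.full(n_alleles, 1.5))
            base = np.clip(base, 0.02, None)
            base /= base.sum()
        alpha = np.clip(base * conc, 1e-3, None)
        fn.append(rng.dirichlet(alpha))
        fs.append(rng.dirichlet(alpha))
    return fn, fs


def simulate_parental_frequencies(
    n_loci: int,
    divergence_target: float,
    marker_kind: str = "snp",
    seed: int | None = None,
    diagnostic: bool = False,
    n_alleles: int | None = None,
    tol: float = 0.01,
) -> LineageFrequencies:
    """Draw per-locus lineage frequencies at a target panel divergence.

    The Balding–Nichols drift parameter is calibrated by bisection so the
    realized mean per-locus F_ST of the drawn vectors lands within ``tol``
    of ``divergence_target`` (the unweighted per-locus mean is the summary
    conventionally reported for diagnostic panels, alongside its range).
    With ``diagnostic=True`` every locus is fixed for alternative alleles.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0 <= divergence_target <= 1:
        raise ValueError("divergence_target must be in [0, 1]")
    if marker_kind not in ("snp", "microsat", "mtdna"):
        raise ValueError(f"unknown marker kind {marker_kind!r}")
    if n_alleles is None:
        n_alleles = 6 if marker_kind == "microsat" else 2
    labels = [f"L{j + 1:03d}" for j in range(n_loci)]
    if diagnostic:
        fn = [np.eye(n_alleles)[0] for _ in range(n_loci)]
        fs = [np.eye(n_alleles)[1] for _ in range(n_loci)]
        return LineageFrequencies(fn, fs, labels, marker_kind)
    rng = np.random.default_rng(seed)
    if divergence_target <= 0:
        fn, _ = _draw_frequencies(n_loci, 1e-4, n_alleles, rng)
        return LineageFrequencies(fn, [v.copy() for v in fn], labels, marker_kind)

    rng_seed = int(rng.integers(2**31 - 1))

    def realized(f: float) -> tuple[float, tuple]:
        # common random numbers across trial f values keep bisection monotone;
        # the calibrated statistic is the unweighted mean of per-locus F_ST
        # (the summary conventionally reported for a diagnostic panel)
        sub = np.random.default_rng(rng_seed)
        fn, fs = _draw_frequencies(n_loci, f, n_alleles, sub)
        num, den = _fst_components(fn, fs)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_locus = np.where(den > 0, num / den, 0.0)
        return float(per_locus.mean()), (fn, fs)
    lo, hi = 1e-4, 0.999
    best = None
    for _ in range(40):
        mid = (lo + hi) / 2
        val, draw = realized(mid)
        best = draw
        if abs(val - divergence_target) <= tol:
            break
        if val < divergence_target:
            lo = mid
        else:
            hi = mid
    fn, fs = best
    return LineageFrequencies(fn, fs, labels, marker_kind)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _allele_code(index: int, kind: str) -> int:
    # microsatellite codes mimic fragment sizes (3-digit, dinucleotide ladder)
    return 101 + 2 * index if kind == "microsat" else index + 1


def _draw_copy(freq_vec: np.ndarray, rng: np.random.Generator, kind: str = "snp") -> int:
    """Allele code drawn from a lineage's frequency vector."""
    return _allele_code(int(rng.choice(len(freq_vec), p=freq_vec)), kind)


def simulate_genotype(class_label: str, freqs: LineageFrequencies, rng) -> np.ndarray:
    """One individual's alleles (L, 2) under the ancestry-pair model.

    The class fixes the probabilities of the two gene copies' lineage
    origins per locus; each copy's allele is then drawn from the origin
    lineage's frequencies. Haploid markers collapse to a maternal-lineage
    draw (pure/backcross toward a lineage inherit it; F1/F2/F3 draw the
    maternal lineage at random).
    """
    if class_label not in CLASS_ANCESTRY:
        raise ValueError(f"unknown hybrid class {class_label!r}")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    L = freqs.n_loci
    out = np.zeros((L, 2), dtype=np.int32)
    if freqs.ploidy == 1:
        if class_label in ("pureN", "BC_N"):
            lineage = 0
        elif class_label in ("pureS", "BC_S"):
            lineage = 1
        else:
            lineage = int(rng.integers(2))
        for j in range(L):
            vec = freqs.freqs_north[j] if lineage == 0 else freqs.freqs_south[j]
            out[j, 0] = _draw_copy(vec, rng, freqs.kind)
        return out
    phi = CLASS_ANCESTRY[class_label]
    for j in range(L):
        pair = rng.choice(3, p=phi)  # 0=(N,N) 1=(N,S) 2=(S,S)
        origins = [(0, 0), (0, 1), (1, 1)][pair]
        for k, o in enumerate(origins):
            vec = freqs.freqs_north[j] if o == 0 else freqs.freqs_south[j]
            out[j, k] = _draw_copy(vec, rng, freqs.kind)
    return out


def _genotypes_from_q(q: float, freqs: LineageFrequencies, rng: np.random.Generator) -> np.ndarray:
    """Alleles for one individual whose each gene copy is northern w.p. q."""
    L = freqs.n_loci
    out = np.zeros((L, 2), dtype=np.int32)
    ploidy = freqs.ploidy
    for j in range(L):
        for k in range(ploidy):
            vec = freqs.freqs_north[j] if rng.random() < q else freqs.freqs_south[j]
            out[j, k] = _draw_copy(vec, rng, freqs.kind)
    return out


def _loci_frame(freqs: LineageFrequencies) -> pd.DataFrame:
    return pd.DataFrame(
        {"name": freqs.loci, "kind": freqs.kind, "ploidy": freqs.ploidy}
    )


# ---------------------------------------------------------------------------
# Transects and temporal series
# ---------------------------------------------------------------------------

def simulate_transect(
    sites: int | np.ndarray,
    true_cline: TrueCline,
    n_per_site: int,
    freqs: LineageFrequencies,
    hybrid_model: str = "admixture_Q",
    seed: int | None = None,
    span: float = 2400.0,
    year: int = 2015,
    dropout: float = 0.0,
) -> SimulatedDataset:
    """Simulate a latitudinal transect of sites under a sigmoid ancestry cline.

    ``sites`` may be a count (evenly spaced over ``span`` km) or an array of
    strictly increasing transect distances. ``hybrid_model='admixture_Q'``
    gives every individual at distance x the true admixture proportion
    q(x); ``'class_mixture'`` draws hybrid classes with Hardy–Weinberg
    ancestry-pair weights (pureN q^2, F1 2q(1-q), pureS (1-q)^2), so the
    expected ancestry frequency also equals q(x). ``dropout`` injects
    uniform missing genotypes.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(sites):
        if sites < 3:
            raise ValueError("need at least 3 sites")
        x = np.linspace(0, span, int(sites))
    else:
        x = np.asarray(sites, dtype=float)
        if len(x) < 3 or np.any(np.diff(x) <= 0):
            raise ValueError("site distances must be strictly increasing, >= 3 sites")
    warnings: list[str] = []
    if not (x.min() <= true_cline.centre <= x.max()):
        warnings.append(
            f"cline centre {true_cline.centre} km outside transect "
            f"[{x.min()}, {x.max()}] km"
        )
    q_site = true_cline.northern_ancestry(x)
    ids, site_col, classes, qs, rows = [], [], [], [], []
    codes = [f"S{k + 1:02d}" for k in range(len(x))]
    for k, code in enumerate(codes):
        for i in range(n_per_site):
            ids.append(f"{code}_{i + 1:03d}")
            site_col.append(code)
            q = float(q_site[k])
            if hybrid_model == "admixture_Q":
                rows.append(_genotypes_from_q(q, freqs, rng))
                classes.append("admixed")
                qs.append(q)
            elif hybrid_model == "class_mixture":
                cls = ["pureN", "F1", "pureS"][
                    rng.choice(3, p=[q * q, 2 * q * (1 - q), (1 - q) ** 2])
                ]
                rows.append(simulate_genotype(cls, freqs, rng))
                classes.append(cls)
                qs.append({"pureN": 1.0, "F1": 0.5, "pureS": 0.0}[cls])
            else:
                raise ValueError(f"unknown hybrid_model {hybrid_model!r}")
    alleles = np.stack(rows)
    if dropout > 0:
        mask = rng.random((alleles.shape[0], alleles.shape[1])) < dropout
        alleles[mask] = 0
    inds = pd.DataFrame({"id": ids, "site": site_col, "year": year, "stage": "adult"})
    matrix = GenotypeMatrix(inds, _loci_frame(freqs), alleles)
    # a nominal coastline running north along ~66W
    site_table = pd.DataFrame(
        {
            "code": codes,
            "distance_km": x,
            "lat": 39.5 + x / 111.0,
            "lon": -66.0,
            "year": year,
            "stage": "adult",
            "n": n_per_site,
        }
    )
    truth = pd.DataFrame({"id": ids, "site": site_col, "true_class": classes, "true_q": qs})
    return SimulatedDataset(matrix, site_table, truth, freqs, true_cline,
                            seed if seed is not None else -1, warnings)


def simulate_temporal_series(
    base: TrueCline,
    years: list[int],
    centre_rate: float,
    width_rate: float = 0.0,
    **transect_kwargs,
) -> dict[int, SimulatedDataset]:
    """One transect dataset per year with a linearly drifting true cline.

    True centre at year t is ``base.centre + centre_rate * (t - years[0])``
    (rates in km/year; a southward shift toward the transect origin is a
    negative ``centre_rate`` here), and analogously for the width.
    """
    years = list(years)
    if any(b <= a for a, b in zip(years, years[1:])):
        raise ValueError("years must be strictly increasing")
    seed = transect_kwargs.pop("seed", None)
    rng = np.random.default_rng(seed)
    out = {}
    for t in years:
        cline_t = TrueCline(
            centre=base.centre + centre_rate * (t - years[0]),
            width=base.width + width_rate * (t - years[0]),
            orientation=base.orientation,
            p_min=base.p_min,
            p_max=base.p_max,
        )
        out[t] = simulate_transect(
            true_cline=cline_t, seed=int(rng.integers(2**31 - 1)),
            year=t, **transect_kwargs
        )
    return out
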