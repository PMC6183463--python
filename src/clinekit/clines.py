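"""Maximum-likelihood geographic cline fitting.

Model
-----
The fitted quantity is a marker frequency (southern-haplotype frequency,
southern-allele frequency, or mean admixture proportion) at sites along a
one-dimensional transect. The central cline is a tanh sigmoid,

    p(x) = pMin + (pMax - pMin) * Sigma(x),

with the unit shape ``Sigma(x) = (1 + tanh(2 (x - c)/w))/2`` for an
increasing cline of centre ``c`` (km) and width ``w`` (km, the inverse of
the maximum slope). Decreasing clines use ``1 - Sigma``. Optional
exponential tails replace the sigmoid beyond junctions at ``c - delta_L``
and ``c + delta_R``: the left tail decays toward the low end with rate
``4 tau_L / w`` and is value-matched at the junction (continuous, not
slope-matched), mirrored on the right.

The model space crosses three scalings of the frequency interval (fixed at
0/1, freely estimated, or pinned to the observed extremes) with five tail
options (neither, both, left, right, mirrored — the mirror shares one
``delta, tau`` pair), giving 15 models plus a constant-frequency null.
Fits maximize a binomial composite log-likelihood in which each site
contributes with weight ``n_eff`` (its effective allele-copy count), and
models are compared by AICc with n = number of sites. Two-log-likelihood
support limits come from the profile likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

P_CLAMP = 1e-9

SCALINGS = ("fixed", "free", "none")
TAILS = ("neither", "both", "left", "right", "mirror")


@dataclass(frozen=True)
class ClineModelSpec:
    """One point of the 3 x 5 model space."""

    scaling: str = "fixed"
    tails: str = "neither"

    def __post_init__(self):
        if self.scaling not in SCALINGS:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.tails not in TAILS:
            raise ValueError(f"unknown tails {self.tails!r}")

    @property
    def n_free_params(self) -> int:
        k = 2  # centre, width
        if self.scaling == "free":
            k += 2
        k += {"neither": 0, "left": 2, "right": 2, "mirror": 2, "both": 4}[self.tails]
        return k

    def __str__(self) -> str:
        name = {"fixed": "fixed scaling", "free": "free scaling", "none": "no scaling"}
        tail = {"neither": "neither tail", "both": "both tails", "left": "left tail only",
                "right": "right tail only", "mirror": "mirror tails"}
        return f"{name[self.scaling]}, {tail[self.tails]}"


MODEL_SPACE = tuple(ClineModelSpec(s, t) for s in SCALINGS for t in TAILS)


@dataclass
class ClineParams:
    centre: float
    width: float
    p_min: float = 0.0
    p_max: float = 1.0
    delta_l: float | None = None
    tau_l: float | None = None
    delta_r: float | None = None
    tau_r: float | None = None
    orientation: str = "decreasing"


@dataclass
class SiteFrequencyProfile:
    """Observed per-site frequencies along the transect.

    ``p_obs`` is the frequency of the marker being modelled (already in the
    fitted orientation); ``n_eff`` the effective allele-copy count used as
    the likelihood weight.
    """

    x: np.ndarray
    p_obs: np.ndarray
    n_eff: np.ndarray
    marker: str = ""
    year: int | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.p_obs = np.asarray(self.p_obs, dtype=float)
        self.n_eff = np.asarray(self.n_eff, dtype=float)
        order = np.argsort(self.x)
        self.x, self.p_obs, self.n_eff = self.x[order], self.p_obs[order], self.n_eff[order]
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("site distances must be distinct")
        if np.any((self.p_obs < 0) | (self.p_obs > 1)):
            raise ValueError("observed frequencies outside [0, 1]")
        if np.any(self.n_eff <= 0):
            raise ValueError("n_eff must be > 0")

    @property
    def n_sites(self) -> int:
        return len(self.x)

    @property
    def span(self) -> float:
        return float(self.x[-1] - self.x[0])


@dataclass
class ClineFit:
    spec: ClineModelSpec | None        # None marks the null (constant) model
    params: ClineParams | None
    log_likelihood: float
    k: int
    aicc: float
    n_sites: int
    converged: bool = True
    centre_limits: tuple[float, float] | None = None
    width_limits: tuple[float, float] | None = None
    boundary_flags: dict = field(default_factory=dict)
    null_p: float | None = None

    @property
    def centre(self) -> float | None:
        return self.params.centre if self.params is not None else None

    @property
    def width(self) -> float | None:
        return self.params.width if self.params is not None else None


@dataclass
class PublishedCline:
    """A previously published cline estimate (centre/width with intervals),
    comparable against fitted clines via :func:`compare_clines`."""

    centre: float
    width: float
    centre_limits: tuple[float, float]
    width_limits: tuple[float, float]
    label: str = ""


# ---------------------------------------------------------------------------
# Cline evaluation and likelihood
# ---------------------------------------------------------------------------

def _unit_shape(x: np.ndarray, c: float, w: float,
                delta_l=None, tau_l=None, delta_r=None, tau_r=None) -> np.ndarray:
    s = (1 + np.tanh(2 * (x - c) / w)) / 2
    if delta_l is not None:
        xl = c - delta_l
        sj = (1 + np.tanh(-2 * delta_l / w)) / 2
        expo = np.clip(4 * tau_l * (x - xl) / w, None, 0)  # used only where x < xl
        s = np.where(x < xl, sj * np.exp(expo), s)
    if delta_r is not None:
        xr = c + delta_r
        sj = (1 + np.tanh(2 * delta_r / w)) / 2
        expo = np.clip(-4 * tau_r * (x - xr) / w, None, 0)
        s = np.where(x > xr, 1 - (1 - sj) * np.exp(expo), s)
    return s


def cline_value(params: ClineParams, x) -> np.ndarray | float:
    """Evaluate the cline model at transect distance(s) x (km)."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    s = _unit_shape(x_arr, params.centre, params.width, params.delta_l,
                    params.tau_l, params.delta_r, params.tau_r)
    if params.orientation == "decreasing":
        s = 1 - s
    p = params.p_min + (params.p_max - params.p_min) * s
    return p if np.ndim(x) else float(p[0])


def neg_log_likelihood(params: ClineParams, profile: SiteFrequencyProfile) -> float:
    """Weighted binomial composite negative log-likelihood."""
    p_hat = np.clip(np.atleast_1d(cline_value(params, profile.x)), P_CLAMP, 1 - P_CLAMP)
    ll = profile.n_eff * (profile.p_obs * np.log(p_hat)
                          + (1 - profile.p_obs) * np.log(1 - p_hat))
    return float(-ll.sum())


def aicc(log_likelihood: float, k: int, n_sites: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); undefined for n <= k+1."""
    if n_sites <= k + 1:
        raise ValueError(f"AICc undefined: n={n_sites} <= k+1={k + 1}")
    return -2 * log_likelihood + 2 * k + 2 * k * (k + 1) / (n_sites - k - 1)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _param_layout(spec: ClineModelSpec, profile: SiteFrequencyProfile):
    """Names and bounds of the free-parameter vector for a model spec."""
    span = max(profile.span, 1.0)
    x0, x1 = profile.x[0], profile.x[-1]
    names = ["centre", "width"]
    bounds = [(x0 - span / 2, x1 + span / 2), (1.0, 4 * span)]
    if spec.scaling == "free":
        names += ["p_min", "p_span"]
        bounds += [(0.0, 1.0), (1e-3, 1.0)]
    if spec.tails in ("left", "mirror", "both"):
        names += ["delta_l", "tau_l"]
        bounds += [(0.0, span), (1e-3, 1.0)]
    if spec.tails in ("right", "both"):
        names += ["delta_r", "tau_r"]
        bounds += [(0.0, span), (1e-3, 1.0)]
    return names, bounds


def _vector_to_params(theta, names, spec: ClineModelSpec,
                      profile: SiteFrequencyProfile, orientation: str) -> ClineParams:
    d = dict(zip(names, theta))
    if spec.scaling == "fixed":
        p_min, p_max = 0.0, 1.0
    elif spec.scaling == "none":
        p_min, p_max = float(profile.p_obs.min()), float(profile.p_obs.max())
        if p_max <= p_min:
            p_max = min(1.0, p_min + 1e-6)
    else:
        p_min = d["p_min"]
        p_max = min(1.0, p_min + d["p_span"])
    delta_l = tau_l = delta_r = tau_r = None
    if spec.tails in ("left", "mirror", "both"):
        delta_l, tau_l = d["delta_l"], d["tau_l"]
    if spec.tails == "mirror":
        delta_r, tau_r = d["delta_l"], d["tau_l"]
    if spec.tails in ("right", "both"):
        delta_r, tau_r = d["delta_r"], d["tau_r"]
    return ClineParams(d["centre"], d["width"], p_min, p_max,
                       delta_l, tau_l, delta_r, tau_r, orientation)


def _fit_objective(spec, names, profile, orientation):
    def nll(theta):
        params = _vector_to_params(theta, names, spec, profile, orientation)
        pen = 0.0
        if spec.scaling == "free":
            over = dict(zip(names, theta))["p_min"] + dict(zip(names, theta))["p_span"] - 1.0
            if over > 0:  # discourage the clipped plateau at p_max = 1
                pen = 10.0 * over
        return neg_log_likelihood(params, profile) + pen
    return nll


def _ml_theta(fit: ClineFit, names) -> np.ndarray:
    """The ML solution re-expressed in the optimizer's parameter vector."""
    vals = []
    for nm in names:
        if nm == "p_span":
            vals.append(fit.params.p_max - fit.params.p_min)
        else:
            vals.append(getattr(fit.params, nm))
    return np.array(vals, dtype=float)


def fit_cline(profile: SiteFrequencyProfile, spec: ClineModelSpec,
              n_starts: int = 32, seed: int | None = None,
              orientation: str = "decreasing",
              compute_limits: bool = False) -> ClineFit:
    """Fit one cline model by bounded multi-start local optimization.

    Starts are a seeded Latin hypercube over the parameter box; each start
    is polished with L-BFGS-B and the best optimum kept. ``orientation``
    states whether the fitted frequency decreases with transect distance
    (the convention for a southern-marker frequency measured from the
    southern terminus).
    """
    k = spec.n_free_params
    if profile.n_sites < k + 2:
        raise ValueError(
            f"{profile.n_sites} sites cannot support model '{spec}' with k={k} "
            f"(need >= {k + 2} for AICc)"
        )
    names, bounds = _param_layout(spec, profile)
    nll = _fit_objective(spec, names, profile, orientation)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    starts = lo + sampler.random(n=n_starts) * (hi - lo)
    # plus a deterministic start at the midpoint-frequency site
    mid = (lo + hi) / 2
    mid[0] = profile.x[np.argmin(np.abs(profile.p_obs - 0.5))]
    mid[1] = max(profile.span / 3, 1.0)
    starts = np.vstack([mid, starts])
    best = None
    converged = False
    for theta0 in starts:
        res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    params = _vector_to_params(best.x, names, spec, profile, orientation)
    logL = -neg_log_likelihood(params, profile)
    fit = ClineFit(spec, params, logL, k, aicc(logL, k, profile.n_sites),
                   profile.n_sites, converged)
    if compute_limits:
        fit.centre_limits = support_limits(fit, profile, "centre")
        fit.width_limits = support_limits(fit, profile, "width")
    return fit


def fit_null(profile: SiteFrequencyProfile) -> ClineFit:
    """Constant-frequency null model (k = 1), weighted-mean closed form."""
    p0 = float(np.clip(np.average(profile.p_obs, weights=profile.n_eff),
                       P_CLAMP, 1 - P_CLAMP))
    ll = profile.n_eff * (profile.p_obs * np.log(p0) + (1 - profile.p_obs) * np.log(1 - p0))
    logL = float(ll.sum())
    return ClineFit(None, None, logL, 1, aicc(logL, 1, profile.n_sites),
                    profile.n_sites, True, null_p=p0)


def model_selection(profile: SiteFrequencyProfile, n_starts: int = 32,
                    seed: int | None = None, orientation: str = "decreasing",
                    compute_limits: bool = True) -> tuple[ClineFit, pd.DataFrame]:
    """Fit the null model plus all 15 cline models; select by AICc.

    Returns the best fit (support limits attached when requested) and the
    full 16-row model table sorted by AICc. Per-model failures are recorded
    in the table rather than aborting. AICc ties within 1e-6 break toward
    fewer parameters.
    """
    rows = []
    fits: list[ClineFit | None] = []
    null = fit_null(profile)
    rows.append({"model": "null", "scaling": "", "tails": "", "k": 1,
                 "logL": null.log_likelihood, "AICc": null.aicc, "error": ""})
    fits.append(null)
    rng = np.random.default_rng(seed)
    for spec in MODEL_SPACE:
        sub = int(rng.integers(2**31 - 1))
        try:
            fit = fit_cline(profile, spec, n_starts=n_starts, seed=sub,
                            orientation=orientation)
            rows.append({"model": str(spec), "scaling": spec.scaling,
                         "tails": spec.tails, "k": fit.k,
                         "logL": fit.log_likelihood, "AICc": fit.aicc, "error": ""})
            fits.append(fit)
        except Exception as exc:  # recorded, not raised
            rows.append({"model": str(spec), "scaling": spec.scaling,
                         "tails": spec.tails, "k": spec.n_free_params,
                         "logL": np.nan, "AICc": np.nan, "error": str(exc)})
            fits.append(None)
    table = pd.DataFrame(rows)
    best_idx, best_aicc, best_k = None, np.inf, np.inf
    for i in range(len(table)):
        a, kk = table.loc[i, "AICc"], table.loc[i, "k"]
        if np.isnan(a):
            continue
        if a < best_aicc - 1e-6 or (abs(a - best_aicc) <= 1e-6 and kk < best_k):
            best_idx, best_aicc, best_k = i, a, kk
    best = fits[best_idx]
    table = table.sort_values(["AICc", "k"], kind="mergesort",
                              na_position="last").reset_index(drop=True)
    if compute_limits and best.spec is not None:
        best.centre_limits = support_limits(best, profile, "centre")
        best.width_limits = support_limits(best, profile, "width")
    return best, table


# ---------------------------------------------------------------------------
# Support limits
# ---------------------------------------------------------------------------

def _profile_nll(fit: ClineFit, profile: SiteFrequencyProfile,
                 parameter: str, value: float) -> float:
    """Minimum NLL with one parameter pinned, others re-optimized."""
    spec = fit.spec
    names, bounds = _param_layout(spec, profile)
    idx = names.index(parameter)
    free = [i for i in range(len(names)) if i != idx]
    nll_full = _fit_objective(spec, names, profile, fit.params.orientation)
    theta_ml = _ml_theta(fit, names)
    if not free:
        theta = theta_ml.copy()
        theta[idx] = value
        return nll_full(theta)

    def obj(sub):
        theta = theta_ml.copy()
        theta[free] = sub
        theta[idx] = value
        return nll_full(theta)

    sub_bounds = [bounds[i] for i in free]
    x0 = np.clip(theta_ml[free], [b[0] for b in sub_bounds], [b[1] for b in sub_bounds])
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=sub_bounds)
    return float(res.fun)


def support_limits(fit: ClineFit, profile: SiteFrequencyProfile,
                   parameter: str = "centre", delta: float = 2.0) -> tuple[float, float]:
    """Profile-likelihood interval: parameter values whose profile logL is
    within ``delta`` of the maximum (delta = 2 is the two-log-likelihood
    rule). Limits hitting the optimization bound are flagged on the fit."""
    if parameter not in ("centre", "width"):
        raise ValueError("parameter must be 'centre' or 'width'")
    names, bounds = _param_layout(fit.spec, profile)
    idx = names.index(parameter)
    lo_b, hi_b = bounds[idx]
    ml_value = getattr(fit.params, parameter)
    nll_min = neg_log_likelihood(fit.params, profile)
    if delta == 0:
        return (ml_value, ml_value)

    def excess(v):
        return _profile_nll(fit, profile, parameter, v) - nll_min - delta

    span = max(profile.span, 1.0)
    out = []
    for direction, bound in ((-1, lo_b), (+1, hi_b)):
        step = max(span / 50, 1e-3)
        a = ml_value
        hit_bound = False
        fb = -delta
        while True:
            b = a + direction * step
            if (direction < 0 and b <= bound) or (direction > 0 and b >= bound):
                b = bound
                hit_bound = True
            fb = excess(b)
            if fb >= 0 or hit_bound:
                break
            a = b
            step *= 1.8
        if fb < 0:  # interval still open at the optimization bound
            fit.boundary_flags[parameter + ("_low" if direction < 0 else "_high")] = True
            out.append(bound)
        else:
            lim = optimize.brentq(excess, min(a, b), max(a, b),
                                  xtol=span * 1e-5 + 1e-6)
            out.append(lim)
    low, high = sorted(out)
    return (min(low, ml_value), max(high, ml_value))


# ---------------------------------------------------------------------------
# Effective sample size
# ---------------------------------------------------------------------------

def effective_sample_size(ref_counts: np.ndarray, ploidy: int = 2):
    """Per-locus effective allele-copy counts for one site.

    Diploid loci: ``n_eff = 2N / (1 + F_IS)`` with
    ``F_IS = 1 - H_obs/H_exp`` clamped to [0, 1], so sites deviating more
    from Hardy–Weinberg proportions are down-weighted. Haploid: ``n_eff =
    N``. Monomorphic loci take the HWE value ``2N`` and are flagged.

    Parameters
    ----------
    ref_counts : (N, L) array of per-individual reference-allele counts
        (NaN = missing).

    Returns
    -------
    (n_eff, flags) : per-locus weights and per-locus monomorphic flags.
    """
    g = np.asarray(ref_counts, dtype=float)
    typed = ~np.isnan(g)
    n = typed.sum(axis=0).astype(float)
    if np.any(n < 2):
        raise ValueError("need >= 2 typed individuals per locus")
    if ploidy == 1:
        return n, np.zeros(g.shape[1], dtype=bool)
    p = np.nansum(g, axis=0) / (2 * n)
    h_exp = 2 * p * (1 - p)
    h_obs = np.nansum(g == 1, axis=0) / n
    mono = h_exp <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        fis = np.clip(1 - h_obs / np.where(mono, np.nan, h_exp), 0.0, 1.0)
    fis = np.where(mono, 0.0, fis)
    return 2 * n / (1 + fis), mono


# ---------------------------------------------------------------------------
# Comparison and temporal dynamics
# ---------------------------------------------------------------------------

def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def compare_clines(fit_a, fit_b) -> dict:
    """Coincidence/concordance by overlap of two-log-likelihood intervals.

    Accepts :class:`ClineFit` objects or any objects exposing
    ``centre_limits`` and ``width_limits`` tuples (e.g.
    :class:`PublishedCline`), so previously published interval estimates
    can be compared directly.
    """
    for f in (fit_a, fit_b):
        if f.centre_limits is None or f.width_limits is None:
            raise ValueError("both fits must carry support limits")
    return {
        "coincident": _intervals_overlap(fit_a.centre_limits, fit_b.centre_limits),
        "concordant": _intervals_overlap(fit_a.width_limits, fit_b.width_limits),
    }


@dataclass
class TemporalClineSeries:
    """Ordered year -> fit mapping; fits need only expose ``.centre``."""

    fits: dict[int, object]

    def __post_init__(self):
        years = list(self.fits)
        if len(set(years)) != len(years):
            raise ValueError("duplicate years")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")

    @property
    def years(self) -> list[int]:
        return list(self.fits)


def rate_of_change(series: TemporalClineSeries) -> pd.DataFrame:
    """Per-interval cline-centre rate of change (km/year).

    Sign convention: positive = southward (centre moving toward the
    southern transect origin), so the rate is
    ``(centre_t - centre_{t+1}) / (year_{t+1} - year_t)``.
    """
    years = series.years
    if len(years) < 2:
        raise ValueError("need >= 2 fits")
    rows = []
    for y0, y1 in zip(years, years[1:]):
        c0 = series.fits[y0].centre
        c1 = series.fits[y1].centre
        rows.append({"from_year": y0, "to_year": y1,
                     "rate_km_per_year": (c0 - c1) / (y1 - y0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-locus clines
# ---------------------------------------------------------------------------

def site_frequency_profiles_per_locus(matrix, distances) -> tuple[dict, dict]:
    """Build one :class:`SiteFrequencyProfile` per polymorphic locus.

    The fitted allele is oriented as the *southern* allele per locus: if
    the reference allele has frequency < 0.5 at the southernmost typed
    site, the profile is flipped so it decreases with distance. Sites with
    fewer than 2 typed individuals at a locus are dropped for that locus.

    Returns ``(profiles, skipped)``; ``skipped`` maps locus -> reason.
    """
    if isinstance(distances, dict):
        distances = pd.Series(distances)
    ref = matrix.ref_counts()
    sites = matrix.individuals["site"].to_numpy()
    site_codes = [s for s in distances.sort_values().index if s in set(sites)]
    profiles: dict[str, SiteFrequencyProfile] = {}
    skipped: dict[str, str] = {}
    for j, name in enumerate(matrix.loci["name"]):
        ploidy = int(matrix.loci["ploidy"].iloc[j])
        freqs, neffs, xs = [], [], []
        for code in site_codes:
            g = ref[sites == code, j]
            g = g[~np.isnan(g)]
            if len(g) < 2:
                continue
            freqs.append(g.sum() / (ploidy * len(g)))
            ne, _ = effective_sample_size(g[:, None], ploidy=ploidy)
            neffs.append(float(ne[0]))
            xs.append(float(distances[code]))
        if len(xs) < 4:
            skipped[name] = "fewer than 4 typed sites"
            continue
        freqs = np.array(freqs)
        if np.all(freqs == freqs[0]):
            skipped[name] = "monomorphic across sites"
            continue
        if freqs[int(np.argmin(xs))] < 0.5:  # orient toward the southern allele
            freqs = 1 - freqs
        profiles[name] = SiteFrequencyProfile(np.array(xs), freqs,
                                              np.array(neffs), marker=name)
    return profiles, skipped


def fit_per_locus_clines(matrix, distances, n_starts: int = 16,
                         seed: int | None = None,
                         spec: ClineModelSpec | None = None) -> tuple[pd.DataFrame, dict]:
    """Best-model cline fit per locus; returns the fit table and skip log.

    ``spec=None`` runs the full 16-model selection per locus (loci where
    the null wins are excluded from the means, as carrying no clinal
    signal); passing a :class:`ClineModelSpec` restricts all loci to that
    model. The unweighted means of the per-locus ML centres and widths are
    stored in ``table.attrs``.
    """
    profiles, skipped = site_frequency_profiles_per_locus(matrix, distances)
    rng = np.random.default_rng(seed)
    rows = []
    for name, prof in profiles.items():
        sub = int(rng.integers(2**31 - 1))
        try:
            if spec is None:
                best, _ = model_selection(prof, n_starts=n_starts, seed=sub,
                                          compute_limits=False)
                if best.spec is None:
                    skipped[name] = "null model preferred (no clinal signal)"
                    continue
            else:
                best = fit_cline(prof, spec, n_starts=n_starts, seed=sub)
            rows.append({"locus": name, "centre": best.centre, "width": best.width,
                         "model": str(best.spec), "AICc": best.aicc,
                         "logL": best.log_likelihood})
        except Exception as exc:
            skipped[name] = str(exc)
    table = pd.DataFrame(rows)
    if len(table):
        table.attrs["mean_centre"] = float(table["centre"].mean())
        table.attrs["mean_width"] = float(table["width"].mean())
    return table, skipped
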