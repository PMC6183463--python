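# Methods

## The system and the estimands

Two lineages of a coastal invader meet along a one-dimensional coastal
transect measured in least-cost kilometres from the southern terminus.
The quantities of interest are (i) the per-individual composition of each
sample — admixture proportion Q, hybrid class, hybrid index h and
interlineage heterozygosity — and (ii) the shape of the aggregate
geographic cline in southern-marker frequency: its centre c (km), width w
(km), and how both move through time.

## Cline model

The central cline is a tanh sigmoid expressed through the unit shape
`Sigma(x) = (1 + tanh(2 (x - c) / w)) / 2`; a frequency cline is
`p(x) = pMin + (pMax - pMin) * Sigma(x)` for an increasing cline and uses
`1 - Sigma` for a decreasing one (southern-marker frequency measured from
the southern terminus decreases, which is the package default). The width
is the inverse of the maximum slope: `|dp/dx| at c = (pMax - pMin) / w`.

Exponential tails optionally replace the sigmoid outside junctions at
`c - delta_L` and `c + delta_R`: the left tail decays to the low
asymptote with rate `4 tau_L / w` and is value-matched (C0) at the
junction, mirrored on the right. Slope-matching at the junction is *not*
imposed — this is a deliberate simplification documented here because the
source tooling for these models names the tail options without printing a
formula; within this family the AICc comparisons across tail options
remain internally consistent. `tau` lies in (0, 1], `delta >= 0`.

The model space crosses three scalings of the frequency interval —
`fixed` (0 and 1), `free` (both estimated), `none` (pinned to the
observed extremes) — with five tail options (`neither`, `both`, `left`,
`right`, `mirror`; the mirror shares a single delta/tau pair), giving 15
models plus a constant-frequency null with k = 1.

### Likelihood, weights and model selection

Sites contribute a weighted binomial composite log-likelihood,
`sum_i n_eff_i [p_obs_i ln p_hat_i + (1 - p_obs_i) ln(1 - p_hat_i)]`,
with model values clamped to [1e-9, 1 - 1e-9]. The weight `n_eff` is the
effective allele-copy count `2N / (1 + F_IS)` (diploid; `F_IS = 1 -
H_obs/H_exp` clamped to [0, 1]), so sites deviating from Hardy–Weinberg
proportions count for less; haploid markers use N, monomorphic loci take
the HWE value 2N and are flagged. Admixture-proportion profiles are
weighted by the site's mean effective allele count times its sample size.

Fitting is bounded multi-start local optimization (a seeded Latin
hypercube of 32 starts by default, polished with L-BFGS-B) over
`c in [x_min - span/2, x_max + span/2]`, `w in [1, 4 span]` km; free
scaling is parameterized as (pMin, pSpan) with a mild penalty beyond
pMax = 1 to avoid a flat clipped plateau. Models are ranked by
`AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1)` with n = number of sites
(sites are the independent units of the composite likelihood); AICc ties
within 1e-6 break toward fewer parameters.

Support limits are profile-likelihood intervals: the extreme parameter
values whose profile log-likelihood (all other parameters re-optimized
from the ML solution) lies within 2 units of the maximum, found by
outward expansion and Brent bracketing; limits that run into an
optimization bound are flagged. Two clines are *coincident* when their
centre intervals overlap and *concordant* when their width intervals
overlap. The centre rate of change between consecutive samplings is
`(c_t - c_{t+1}) / (year_{t+1} - year_t)` — positive southward — using
integer calendar years.

## Hybrid classification

Each diploid class fixes the ancestry-pair law phi = (P(NN), P(NS),
P(SS)): pure (1,0,0)/(0,0,1), F1 (0,1,0), F2 (1/4,1/2,1/4), backcrosses
(1/2,1/2,0)/(0,1/2,1/2). Per locus, P(genotype | class) marginalizes the
pair with plug-in parental frequencies; loci multiply (the panel is
chosen for low LD) and missing loci are skipped. Parental frequencies are
supplied rather than co-estimated: the transect ends are effectively
pure, so plug-in estimation is adequate and keeps the posterior exact and
testable. Priors default to uniform over the six classes; the threshold
for a call is a posterior of 0.85, and the three-class aggregation sums
the four hybrid classes. F2, backcrosses and F3 form a single
"recombinant" super-class for reporting, since later-generation hybrids
are not reliably separable.

The ML hybrid index h maximizes the binomial likelihood in which every
gene copy is of northern origin with probability h (bounded scalar
optimization to 1e-4, ends checked). Interlineage heterozygosity is
computed over loci with `|p_N - p_S| >= delta_min` (default 0.5, the
conventional restriction to strongly informative loci) as the expected
fraction of loci with one copy of each origin, using per-copy origin
posteriors with prior h; on diagnostic loci it reduces to the exact
heterozygote count, and `het <= 2 min(h, 1-h)` (the triangle constraint).

## Admixture EM

The K = 2 admixture likelihood (each allele copy independently from
cluster 1 with probability Q_i, then an allele from that cluster's
frequency vector) is maximized by EM on per-locus allele-copy count
blocks, which handles multiallelic microsatellites natively and skips
missing copies. The log-likelihood is asserted non-decreasing every
iteration; convergence is `|delta logL| < 1e-6` or 2,000 iterations, best
of 8 seeded starts by default. Label switching is resolved by anchoring
cluster 1 to the designated reference group (mean Q >= 0.5 after
anchoring), making output deterministic given the seed. This is a
maximum-likelihood point-estimate stand-in for Bayesian MCMC clustering:
the cline stage consumes only per-site mean Q, for which the ML point
estimate suffices; without the Bayesian admixture prior, individual Q
estimates are slightly less shrunken than MCMC posteriors would be.

## Synthetic data: what it emulates and what it does not

Parental frequencies follow a Balding–Nichols-style model — ancestral
frequency uniform on (0.05, 0.95), lineage frequencies Beta-distributed
around it with concentration (1 - F)/F — with F calibrated by bisection
(common random numbers) so the realized **mean per-locus F_ST** between
the lineages hits the target (default study value 0.344; the panel range
requirement, spanning at least [target/3, 2·target], is inherited from
the drift-model spread). The per-locus mean is the calibrated summary
because diagnostic panels are conventionally reported as a per-locus mean
with a range; the multi-locus ratio-of-sums F_ST of such panels is
substantially higher.

Hybrid genotypes follow the ancestry-pair law above with free
recombination and no within-lineage LD (the panel emulated was selected
for low LD); F3 is the union of two independent F2 gametes, which per
locus equals the F2 law. Transects place sites at strictly increasing
distances and draw either admixed individuals with Q equal to the cline
value at their site, or a pure/F1 class mixture with Hardy–Weinberg
ancestry weights; both make the expected ancestry frequency equal the
true cline. Temporal series move the true centre and width linearly.
Missing data is an optional uniform dropout (default 0) — the emulated
study filtered individuals rather than modelling missingness.

Not emulated: spatially explicit larval advection, linkage maps,
selection, site-specific sample-size variation, genotyping artefacts
beyond uniform dropout. Passing tests therefore demonstrate correctness
of the estimators under the stated statistical structure, not robustness
to real-data pathologies such as clustered missingness or LD.

Study-scale defaults used throughout validation: 96 loci at divergence
0.344, 25 sites over 2,400 km, cline centre 1,300 km, width 600 km,
n_eff 64 copies/site, 50 replicates for coverage experiments. These are
the conditions the emulated study reports, and they keep each experiment
in the minutes range on a single core.

## Coastal distances

Distances are shortest paths over the 8-connected graph of navigable
raster cells (depth strictly positive, within [min_depth, max_depth],
default 0–30 m), with great-circle edge weights and endpoint snapping to
the nearest navigable cell within 3 cells. Per-site maximum-depth
overrides (e.g. 60 m for an island site, 300 m across a deep channel)
relax the band for the *whole* path to that site, mirroring per-region
relaxations rather than a global change. The scheme is an approximation:
8-connectivity overestimates diagonal shore-hugging paths by up to ~8%,
and grid refinement changes open-water distances by <3%; the cline stage
is insensitive to distance errors of this size.

## Numerical choices and degenerate inputs

- Model frequencies clamped at 1e-9; EM frequencies at 1e-9; Q at
  [1e-9, 1 - 1e-9].
- Step-like profiles drive the fitted width to its lower bound (1 km);
  the fit is returned with the boundary flag on its support limit.
- A locus monomorphic across sites, or typed at fewer than 4 sites, is
  excluded from per-locus cline fitting with a recorded reason; loci
  where the null model wins carry no clinal signal and are likewise
  excluded from per-locus means (which are unweighted).
- W-C F_ST accumulates variance components over all alleles and loci
  (ratio of sums); shared monomorphic loci contribute nothing, negative
  estimates are reported as-is.
- Genepop "00"/"000" codes are missing; biallelic polarity is assigned
  downstream from lineage frequencies, never at parse time.

## Known limitations

- Tail junctions are C0, not C1 (see above).
- The admixture EM provides point estimates only; no posterior spread.
- Coincidence/concordance by interval overlap is a conservative
  pairwise criterion, not a formal likelihood-ratio test.
- Admixture-proportion RMSE against uniform truth at the study's panel
  divergence sits near 0.06: close to the Cramér–Rao floor for 96
  biallelic loci at a mean per-locus F_ST of 0.344 (~0.05 even for the
  most favourable panel at that mean), so materially tighter accuracy
  requires more or more-diagnostic loci, not a better estimator.
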