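"""Cline model: closed-form shape checks, likelihood arithmetic, AICc,
model selection, support limits, comparisons, rates, per-locus fits."""

import numpy as np
import pandas as pd
import pytest

from clinekit import clines
from clinekit import simulate as sim
from clinekit.clines import (
    ClineModelSpec,
    ClineParams,
    PublishedCline,
    SiteFrequencyProfile,
    TemporalClineSeries,
)
from clinekit.published import COI_CLINES, MICROSAT_CLINES, PREDICTED_2014


def _noiseless_profile(centre=1300.0, width=600.0, n_sites=25, span=2400.0,
                       n_eff=64.0):
    x = np.linspace(0, span, n_sites)
    p = np.atleast_1d(clines.cline_value(
        ClineParams(centre, width, orientation="decreasing"), x))
    return SiteFrequencyProfile(x, p, np.full(n_sites, n_eff))


class TestClineValue:
    def test_midpoint_is_half(self):
        params = ClineParams(1000.0, 400.0)
        assert clines.cline_value(params, 1000.0) == pytest.approx(0.5)

    def test_saturation_limits_decreasing(self):
        params = ClineParams(1000.0, 400.0, orientation="decreasing")
        assert clines.cline_value(params, -1e9) == pytest.approx(1.0)
        assert clines.cline_value(params, 1e9) == pytest.approx(0.0)

    def test_tanh_identities(self):
        """p(c-w/2)-p(c+w/2) = tanh(1)*(pMax-pMin); |dp/dx| at c = span/w."""
        params = ClineParams(1000.0, 400.0, p_min=0.1, p_max=0.8,
                             orientation="decreasing")
        drop = clines.cline_value(params, 1000 - 200) - clines.cline_value(params, 1000 + 200)
        assert drop == pytest.approx(np.tanh(1.0) * 0.7, abs=1e-4)
        eps = 1e-4
        slope = (clines.cline_value(params, 1000 + eps)
                 - clines.cline_value(params, 1000 - eps)) / (2 * eps)
        assert abs(slope) == pytest.approx(0.7 / 400, abs=1e-6)

    def test_continuity_across_tail_junctions(self):
        params = ClineParams(1200.0, 500.0, delta_l=300.0, tau_l=0.5,
                             delta_r=150.0, tau_r=0.8, orientation="decreasing")
        x = np.arange(0.0, 2400.0, 1.0)
        p = clines.cline_value(params, x)
        assert np.max(np.abs(np.diff(p))) < 0.005  # no jumps on a 1-km grid
        for xj in (1200 - 300, 1200 + 150):
            left = clines.cline_value(params, xj - 1e-9)
            right = clines.cline_value(params, xj + 1e-9)
            assert abs(left - right) < 1e-6

    def test_tail_saturation_with_tails(self):
        params = ClineParams(1200.0, 500.0, delta_l=300.0, tau_l=0.5,
                             orientation="decreasing")
        assert clines.cline_value(params, -1e7) == pytest.approx(1.0)


class TestLikelihoodAndAicc:
    def test_hand_computed_three_site_sum(self):
        prof = SiteFrequencyProfile(np.array([0.0, 100.0, 200.0]),
                                    np.array([0.9, 0.5, 0.2]),
                                    np.array([10.0, 20.0, 30.0]))
        params = ClineParams(100.0, 80.0, orientation="decreasing")
        p_hat = np.atleast_1d(clines.cline_value(params, prof.x))
        expect = -sum(n * (p * np.log(ph) + (1 - p) * np.log(1 - ph))
                      for n, p, ph in zip(prof.n_eff, prof.p_obs, p_hat))
        assert clines.neg_log_likelihood(params, prof) == pytest.approx(expect, abs=1e-10)

    def test_weights_are_linear(self):
        prof = _noiseless_profile(n_eff=16.0)
        prof2 = SiteFrequencyProfile(prof.x, prof.p_obs, prof.n_eff * 2)
        params = ClineParams(1200.0, 500.0, orientation="decreasing")
        assert clines.neg_log_likelihood(params, prof2) == pytest.approx(
            2 * clines.neg_log_likelihood(params, prof), rel=1e-12)

    def test_aicc_worked_example(self):
        assert clines.aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_aicc_null_and_correction(self):
        assert clines.aicc(-5.0, 0, 10) == pytest.approx(10.0)
        for k in (1, 2, 5):
            aic = -2 * (-5.0) + 2 * k
            assert clines.aicc(-5.0, k, 12) > aic

    def test_aicc_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            clines.aicc(-5.0, 4, 5)


class TestFitting:
    def test_noiseless_recovery(self):
        prof = _noiseless_profile()
        fit = clines.fit_cline(prof, ClineModelSpec("fixed", "neither"),
                               n_starts=12, seed=1)
        assert fit.centre == pytest.approx(1300.0, abs=2.0)
        assert fit.width == pytest.approx(600.0, abs=10.0)

    def test_step_data_centre_between_plateaus(self):
        x = np.arange(0.0, 600.0, 100.0)
        p = np.array([1, 1, 1, 0, 0, 0.0])
        prof = SiteFrequencyProfile(x, p, np.full(6, 50.0))
        fit = clines.fit_cline(prof, ClineModelSpec("fixed", "neither"),
                               n_starts=12, seed=2)
        assert 200.0 < fit.centre < 300.0
        assert fit.width <= 2.0  # collapses toward the lower width bound

    def test_too_few_sites_refused(self):
        prof = SiteFrequencyProfile(np.array([0.0, 1.0, 2.0]),
                                    np.array([1.0, 0.5, 0.0]), np.ones(3))
        with pytest.raises(ValueError, match="sites"):
            clines.fit_cline(prof, ClineModelSpec("free", "both"))

    def test_free_scaling_nests_fixed(self):
        rng = np.random.default_rng(3)
        prof = _noiseless_profile()
        noisy = SiteFrequencyProfile(
            prof.x, rng.binomial(64, prof.p_obs) / 64, prof.n_eff)
        f_fixed = clines.fit_cline(noisy, ClineModelSpec("fixed", "neither"),
                                   n_starts=12, seed=4)
        f_free = clines.fit_cline(noisy, ClineModelSpec("free", "neither"),
                                  n_starts=24, seed=5)
        assert f_free.log_likelihood >= f_fixed.log_likelihood - 1e-6


class TestModelSelection:
    def test_table_has_null_plus_fifteen_models(self):
        prof = _noiseless_profile(n_sites=12)
        best, table = clines.model_selection(prof, n_starts=4, seed=6,
                                             compute_limits=False)
        assert len(table) == 16
        assert (table["model"] == "null").sum() == 1
        assert len(clines.MODEL_SPACE) == 15
        specs = {(s.scaling, s.tails) for s in clines.MODEL_SPACE}
        assert len(specs) == 15

    def test_flat_data_keeps_null_competitive(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 2400, 20)
        p = np.clip(0.5 + rng.normal(0, 0.02, 20), 0, 1)
        prof = SiteFrequencyProfile(x, p, np.full(20, 40.0))
        best, table = clines.model_selection(prof, n_starts=6, seed=8,
                                             compute_limits=False)
        null_aicc = float(table.loc[table["model"] == "null", "AICc"].iloc[0])
        assert null_aicc <= table["AICc"].min() + 2.0

    def test_strong_sigmoid_crushes_null(self):
        prof = _noiseless_profile()
        best, table = clines.model_selection(prof, n_starts=6, seed=9,
                                             compute_limits=False)
        null_aicc = float(table.loc[table["model"] == "null", "AICc"].iloc[0])
        assert best.spec is not None
        assert null_aicc - best.aicc > 10.0

    def test_parsimony_on_no_tail_truth(self):
        """In >= 80% of 50 noisy replicates from a fixed-scaling no-tail
        cline, the selected model is within 2 AICc of that generating spec."""
        rng = np.random.default_rng(10)
        prof0 = _noiseless_profile(n_sites=15)
        hits = 0
        for _ in range(50):
            p = rng.binomial(64, prof0.p_obs) / 64
            prof = SiteFrequencyProfile(prof0.x, p, prof0.n_eff)
            best, table = clines.model_selection(prof, n_starts=4, seed=int(rng.integers(2**31 - 1)),
                                                 compute_limits=False)
            gen = table[(table["scaling"] == "fixed") & (table["tails"] == "neither")]
            if float(gen["AICc"].iloc[0]) <= best.aicc + 2.0:
                hits += 1
        assert hits >= 40


class TestSupportLimits:
    def test_zero_delta_degenerates_to_point(self):
        prof = _noiseless_profile(n_sites=15)
        fit = clines.fit_cline(prof, ClineModelSpec("fixed", "neither"),
                               n_starts=8, seed=11)
        lo, hi = clines.support_limits(fit, prof, "centre", delta=0.0)
        assert lo == hi == fit.centre

    def test_limits_bracket_ml_and_shrink_with_information(self):
        widths = []
        for n_eff in (16.0, 64.0, 256.0):
            prof = _noiseless_profile(n_eff=n_eff)
            fit = clines.fit_cline(prof, ClineModelSpec("fixed", "neither"),
                                   n_starts=8, seed=12)
            lo, hi = clines.support_limits(fit, prof, "centre")
            assert lo <= fit.centre <= hi
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_quadratic_surrogate_closed_form(self):
        """On a quadratic logL surface the 2LL limits are
        ml +- sqrt(2*delta/curvature)."""
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        prof = SiteFrequencyProfile(x, np.array([1.0, 0.9, 0.5, 0.1, 0.0]),
                                    np.full(5, 30.0))
        fit = clines.fit_cline(prof, ClineModelSpec("fixed", "neither"),
                               n_starts=12, seed=13)
        lo, hi = clines.support_limits(fit, prof, "centre", delta=2.0)
        # curvature from central differences of the centre profile NLL
        h = 0.01
        f0 = clines._profile_nll(fit, prof, "centre", fit.centre)
        fp = clines._profile_nll(fit, prof, "centre", fit.centre + h)
        fm = clines._profile_nll(fit, prof, "centre", fit.centre - h)
        curv = (fp + fm - 2 * f0) / h**2
        half = np.sqrt(2 * 2.0 / curv)
        assert hi - lo == pytest.approx(2 * half, rel=0.15)


class TestComparisonsAndRates:
    def test_self_comparison_coincident_concordant(self):
        prof = _noiseless_profile(n_sites=15)
        fit = clines.fit_cline(prof, ClineModelSpec("fixed", "neither"),
                               n_starts=8, seed=14, compute_limits=True)
        out = clines.compare_clines(fit, fit)
        assert out == {"coincident": True, "concordant": True}

    def test_observed_2007_vs_predicted_non_coincident_but_concordant(self):
        out = clines.compare_clines(COI_CLINES[2007], PREDICTED_2014)
        assert out["coincident"] is False
        assert out["concordant"] is True

    def test_identical_centres_zero_rate(self):
        s = TemporalClineSeries({2007: PublishedCline(1000, 500, (1, 2), (1, 2)),
                                 2015: PublishedCline(1000, 500, (1, 2), (1, 2))})
        assert clines.rate_of_change(s)["rate_km_per_year"].iloc[0] == 0.0

    def test_published_microsat_rate_14(self):
        s = TemporalClineSeries({y: MICROSAT_CLINES[y] for y in (2007, 2015)})
        assert clines.rate_of_change(s)["rate_km_per_year"].iloc[0] == pytest.approx(14.0)

    def test_published_coi_rates_and_prediction_ratio(self):
        s = TemporalClineSeries({y: COI_CLINES[y] for y in (2007, 2015)})
        observed = clines.rate_of_change(s)["rate_km_per_year"].iloc[0]
        assert observed == pytest.approx(21.75)
        s2 = TemporalClineSeries({2007: COI_CLINES[2007], 2014: PREDICTED_2014})
        predicted = clines.rate_of_change(s2)["rate_km_per_year"].iloc[0]
        assert predicted / observed >= 3.0

    def test_rates_scale_inversely_with_time(self):
        fits = {2000: PublishedCline(1600, 1, (0, 1), (0, 1)),
                2004: PublishedCline(1400, 1, (0, 1), (0, 1)),
                2008: PublishedCline(1100, 1, (0, 1), (0, 1))}
        r1 = clines.rate_of_change(TemporalClineSeries(fits))
        stretched = {2000 + 3 * (y - 2000): f for y, f in fits.items()}
        r3 = clines.rate_of_change(TemporalClineSeries(stretched))
        assert np.allclose(r3["rate_km_per_year"], r1["rate_km_per_year"] / 3)

    def test_duplicate_years_rejected(self):
        with pytest.raises(ValueError):
            TemporalClineSeries({2007: None, 2007: None, 2006: None})


class TestEffectiveSampleSize:
    def test_hwe_site_gives_2n(self):
        # 32 individuals exactly at HWE proportions: 8/16/8 for p=0.5
        g = np.array([2.0] * 8 + [1.0] * 16 + [0.0] * 8)[:, None]
        n_eff, mono = clines.effective_sample_size(g)
        assert n_eff[0] == pytest.approx(64.0)
        assert not mono[0]

    def test_full_heterozygote_deficit_halves_weight(self):
        g = np.array([2.0] * 16 + [0.0] * 16)[:, None]  # H_obs = 0, F_IS = 1
        n_eff, _ = clines.effective_sample_size(g)
        assert n_eff[0] == pytest.approx(32.0)

    def test_monomorphic_flagged_with_2n_convention(self):
        g = np.full((10, 1), 2.0)
        n_eff, mono = clines.effective_sample_size(g)
        assert n_eff[0] == pytest.approx(20.0) and mono[0]

    def test_haploid_uses_n(self):
        g = np.array([1.0, 0.0, 1.0, 1.0])[:, None]
        n_eff, _ = clines.effective_sample_size(g, ploidy=1)
        assert n_eff[0] == 4

    def test_sampled_hwe_site_near_full_weight(self, rng):
        """n_eff/2N in [0.9, 1] for >= 95% of 200 binomial HWE samples.

        N = 400 keeps the F_IS estimator's sampling noise (SD ~ 1/sqrt(N))
        below the 0.11 excess that would push the ratio under 0.9.
        """
        N = 400
        ok = 0
        for _ in range(200):
            g = rng.binomial(2, 0.5, size=N).astype(float)[:, None]
            n_eff, _ = clines.effective_sample_size(g)
            if 0.9 <= n_eff[0] / (2 * N) <= 1.0:
                ok += 1
        assert ok >= 190


class TestPerLocusClines:
    def test_mean_centre_recovered_and_monomorphic_excluded(self, rng):
        freqs = sim.simulate_parental_frequencies(8, 1.0, diagnostic=True)
        ds = sim.simulate_transect(16, sim.TrueCline(1300, 600), 24, freqs,
                                   seed=15, span=2400.0)
        m = ds.matrix
        # append a monomorphic locus
        loci = pd.concat([m.loci, pd.DataFrame({"name": ["MONO"], "kind": ["snp"],
                                                "ploidy": [2]})], ignore_index=True)
        alleles = np.concatenate([m.alleles, np.ones((m.n_individuals, 1, 2),
                                                     dtype=np.int32)], axis=1)
        m = type(m)(m.individuals, loci, alleles)
        distances = dict(zip(ds.sites["code"], ds.sites["distance_km"]))
        table, skipped = clines.fit_per_locus_clines(
            m, distances, n_starts=4, seed=16,
            spec=ClineModelSpec("fixed", "neither"))
        assert "MONO" in skipped and "monomorphic" in skipped["MONO"]
        assert len(table) == 8
        assert table.attrs["mean_centre"] == pytest.approx(1300.0, rel=0.02)

    def test_centre_spread_wider_at_lower_divergence(self, rng):
        """Per-locus centre estimates scatter more when loci are less
        differentiated (controlled symmetric panels, delta_p 0.9 vs 0.4)."""
        spreads = []
        for dp, seed in ((0.9, 21), (0.4, 22)):
            fn = [np.array([0.5 + dp / 2, 0.5 - dp / 2])] * 10
            fs = [np.array([0.5 - dp / 2, 0.5 + dp / 2])] * 10
            freqs = sim.LineageFrequencies(fn, fs, [f"L{j}" for j in range(10)])
            ds = sim.simulate_transect(14, sim.TrueCline(1300, 600), 32, freqs,
                                       seed=seed + 1, span=2400.0)
            distances = dict(zip(ds.sites["code"], ds.sites["distance_km"]))
            table, _ = clines.fit_per_locus_clines(
                ds.matrix, distances, n_starts=4, seed=seed + 2,
                spec=ClineModelSpec("fixed", "neither"))
            spreads.append(table["centre"].std())
        assert spreads[1] > spreads[0]
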