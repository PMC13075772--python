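import math

import numpy as np
import pandas as pd
import pytest

from audthal import fra, synth
from audthal.fra import (CFCriteria, RateLevelModel, compute_fra, derive_sensitivity,
                         detect_responsive, lognormal_rate,
                         select_characteristic_frequency, tuning_bandwidth)
from audthal.stimuli import PT, build_stimulus_grid

SPLS = np.arange(40.0, 76.0, 5.0)


def _spike_df(rows):
    return pd.DataFrame(rows, columns=["unit_id", "kind", "freq_hz", "spl_db",
                                       "trial", "spike_ms"])


class TestComputeFRA:
    def test_silent_unit_flagged_degenerate(self, grid):
        df = _spike_df([(0, PT, 560.0, 40.0, 0, 10.0)])
        df = df[df["unit_id"] == 1]  # empty
        f = compute_fra(df, grid, 0, PT)
        assert f.degenerate
        assert np.all(f.rates == 0) and np.all(f.normalized == 0)

    def test_off_grid_condition_is_an_error(self, grid):
        df = _spike_df([(0, PT, 777.0, 40.0, 0, 10.0)])
        with pytest.raises(ValueError, match="off the grid"):
            compute_fra(df, grid, 0, PT)

    def test_nine_spikes_per_trial_gives_100_sp_s(self, grid):
        rows = []
        for t in range(grid.repetitions):
            for k in range(9):
                rows.append((0, PT, 560.0, 40.0, t, 10.0 + k))
        f = compute_fra(_spike_df(rows), grid, 0, PT)
        assert f.rates[0, 0] == pytest.approx(100.0)

    def test_normalization_max_is_one(self, grid, unit_population, unit_analysis):
        f = next(iter(unit_analysis["fras"].values()))
        assert f.normalized.max() == pytest.approx(1.0)

    def test_poisson_round_trip_within_binomial_error(self, grid):
        rng = np.random.default_rng(0)
        rate = 40.0
        rows = []
        for fi, fr in enumerate(grid.center_frequencies):
            for spl in grid.spl_levels:
                for t in range(grid.repetitions):
                    n = rng.poisson(rate * 0.090)
                    for s in rng.uniform(5, 95, n):
                        rows.append((0, PT, fr, spl, t, s))
        f = compute_fra(_spike_df(rows), grid, 0, PT)
        se = math.sqrt(rate / (0.090 * grid.repetitions))
        assert np.all(np.abs(f.rates - rate) < 4 * se)


class TestResponsiveness:
    def _fra_from_counts(self, counts, grid):
        rates = counts.mean(axis=2) / 0.09
        return fra.FRA(unit_id=0, kind=PT, frequencies=np.array(grid.center_frequencies),
                       spls=np.array(grid.spl_levels), rates=rates, counts=counts)

    def test_identical_counts_non_responsive(self, grid):
        counts = np.full((11, 8, 15), 3.0)
        r = detect_responsive(self._fra_from_counts(counts, grid))
        assert not r.responsive and r.zero_variance

    def test_strong_unit_detected(self, grid):
        rng = np.random.default_rng(1)
        counts = rng.poisson(0.2, size=(11, 8, 15)).astype(float)
        counts[5] = rng.poisson(0.2 + 3.0 * np.linspace(0, 1, 8)[:, None],
                                size=(8, 15))
        r = detect_responsive(self._fra_from_counts(counts, grid))
        assert r.responsive
        assert np.argmin(r.p_per_frequency) == 5

    def test_twoway_anova_matches_statsmodels(self, grid):
        """The balanced two-way ANOVA used for the responsiveness omnibus
        agrees with the statsmodels OLS/anova_lm route."""
        import pandas as pd
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(7)
        counts = rng.poisson(1.5, size=(4, 3, 6)).astype(float)
        counts[1] += rng.poisson(2.0, size=(3, 6))
        p_amp, p_freq, p_int = fra._twoway_anova(counts)

        a, b, n = counts.shape
        df = pd.DataFrame({
            "y": counts.ravel(),
            "f": np.repeat(np.arange(a), b * n),
            "s": np.tile(np.repeat(np.arange(b), n), a),
        })
        model = smf.ols("y ~ C(f) * C(s)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        assert p_freq == pytest.approx(tab.loc["C(f)", "PR(>F)"], rel=1e-6)
        assert p_amp == pytest.approx(tab.loc["C(s)", "PR(>F)"], rel=1e-6)
        assert p_int == pytest.approx(tab.loc["C(f):C(s)", "PR(>F)"], rel=1e-6)

    def test_null_units_type_one_error_at_most_nominal(self, grid):
        """On pure-noise units the Bonferroni-corrected responsiveness call
        fires at no more than the nominal alpha (conservative by design)."""
        rng = np.random.default_rng(2)
        n_sim, alpha = 400, 0.01
        hits = 0
        for _ in range(n_sim):
            counts = rng.poisson(1.0, size=(11, 8, 15)).astype(float)
            r = detect_responsive(self._fra_from_counts(counts, grid),
                                  alpha=alpha, omnibus=False)
            hits += r.responsive
        se = math.sqrt(alpha * (1 - alpha) / n_sim)
        assert hits / n_sim <= alpha + 3 * se


class TestRateLevelFit:
    def test_noiseless_parameter_recovery_and_peak_location(self):
        true = (50.0, 4.0, 0.5, 0.05)
        y = lognormal_rate(SPLS, *true)
        res = RateLevelModel(SPLS, y).fit(seed=0)
        assert res.r_squared > 0.9999
        assert np.allclose(res.params, true, rtol=1e-3, atol=1e-3)
        # the fitted curve's peak lies at exp(mu - sigma^2) ~ 42.5 dB
        assert res.sensitivity.peak_db == pytest.approx(math.exp(4.0 - 0.25), abs=0.01)

    def test_flat_data_flagged_uninformative(self):
        y = np.full_like(SPLS, 0.08)
        res = RateLevelModel(SPLS, y).fit(seed=0)
        assert res.r_squared < 0.1 or not res.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            RateLevelModel(SPLS[:3], np.ones(3))

    def test_noisy_c50_recovery_median_within_tolerance(self):
        """At 15 Poisson trials and reference SNR the median absolute C50
        error stays below 5 dB (50 replicate fits)."""
        rng = np.random.default_rng(3)
        errs = []
        for rep in range(50):
            c50, sig = 55.0, 0.22
            nev = 48.0 * 0.09 * synth.lognormal_rate_curve(SPLS, c50, sig)
            counts = rng.poisson(np.tile(nev + 0.18, (15, 1)))
            y = counts.mean(0) / counts.mean(0).max()
            res = RateLevelModel(SPLS, y).fit(n_starts=4, seed=rep)
            errs.append(abs(res.c50 - c50))
        assert np.median(errs) <= 5.0


class TestSensitivity:
    def test_c50_matches_bisection_oracle(self):
        params = np.array([50.0, 4.0, 0.5, 0.05])
        res = derive_sensitivity(params)
        # independent bisection on the analytic curve
        f = lambda x: lognormal_rate(np.array([x]), *params)[0]
        peak = math.exp(4.0 - 0.25)
        level = params[3] + 0.5 * (f(peak) - params[3])
        lo, hi = 1.0, peak
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if f(mid) < level:
                lo = mid
            else:
                hi = mid
        assert res.c50_db == pytest.approx(0.5 * (lo + hi), abs=0.01)

    def test_scale_offset_invariance_of_c50(self):
        """A positive affine map of the curve (E -> aE, B -> aB + b) leaves
        C50 unchanged: the 50%-of-range definition is scale and offset
        free."""
        base = np.array([60.0, 4.1, 0.4, 0.05])
        s0 = derive_sensitivity(base)
        for a, b in [(2.0, 0.0), (0.5, 0.02), (3.0, 0.1)]:
            mapped = np.array([a * base[0], base[1], base[2], a * base[3] + b])
            s = derive_sensitivity(mapped)
            assert s.c50_db == pytest.approx(s0.c50_db, abs=1e-4)

    def test_monotonic_when_curve_stays_high_at_domain_edge(self):
        # very broad curve: still above half-max at 100 dB
        y = lognormal_rate(SPLS, 150.0, 5.2, 0.8, 0.02)
        res = RateLevelModel(SPLS, y).fit(seed=0)
        assert res.monotonic and np.isinf(res.half_width)

    def test_narrow_sigma_is_o_shaped_with_finite_half_width(self):
        y = lognormal_rate(SPLS, 8.0, 4.05, 0.12, 0.02)
        res = RateLevelModel(SPLS, y).fit(seed=0)
        assert not res.monotonic
        assert np.isfinite(res.half_width)

    def test_o_shape_agrees_with_derivative_sign_at_domain_edge(self):
        """On noiseless fits the monotonic/O-shaped call matches the sign of
        the analytic derivative of the fitted curve at the upper edge,
        relative to the half-maximum level."""
        for params in [(8.0, 4.05, 0.12, 0.02), (150.0, 5.2, 0.8, 0.02),
                       (30.0, 4.3, 0.3, 0.05)]:
            y = lognormal_rate(SPLS, *params)
            res = RateLevelModel(SPLS, y).fit(seed=0)
            E, mu, sig, B = res.params
            hi = fra.EVAL_DOMAIN_DB[1]
            f_hi = lognormal_rate(np.array([hi]), *res.params)[0]
            hw_level = 0.5 * res.sensitivity.fitted_max
            if res.monotonic:
                assert f_hi >= hw_level or res.sensitivity.peak_db >= hi
            else:
                assert f_hi < hw_level


class TestCFSelection:
    def _make_fit(self, freq, c50, r2=0.95, rmax=1.0):
        res = fra.RateLevelResult(freq, np.array([10.0, 4.0, 0.3, 0.05]), None,
                                  r2, True, 8)
        res.sensitivity = fra.SensitivityMeasures(c50, np.inf, True, 70.0, rmax)
        return res

    def _fra_stub(self, grid, n_f=11):
        rates = np.zeros((n_f, 8))
        rates[0, 0] = 10.0
        return fra.FRA(unit_id=0, kind=PT,
                       frequencies=np.array(grid.center_frequencies),
                       spls=np.array(grid.spl_levels), rates=rates,
                       counts=np.zeros((n_f, 8, 15)))

    def test_argmin_c50_wins(self, grid):
        fits = [None] * 11
        fits[7] = self._make_fit(6300.0, 50.0)
        fits[8] = self._make_fit(9000.0, 55.0)
        p = np.full(11, 1.0)
        p[7] = p[8] = 0.001
        tun = select_characteristic_frequency(fits, self._fra_stub(grid), p)
        assert tun.cf_hz == 6300.0 and tun.c50_at_cf_db == 50.0

    def test_failing_r2_falls_back_to_next_lowest_c50(self, grid):
        fits = [None] * 11
        fits[7] = self._make_fit(6300.0, 50.0, r2=0.5)   # best C50, bad fit
        fits[8] = self._make_fit(9000.0, 55.0)
        p = np.full(11, 1.0)
        p[7] = p[8] = 0.001
        tun = select_characteristic_frequency(fits, self._fra_stub(grid), p)
        assert tun.cf_hz == 9000.0

    def test_no_passing_frequency_excludes_unit(self, grid):
        fits = [None] * 11
        tun = select_characteristic_frequency(fits, self._fra_stub(grid),
                                              np.full(11, 1.0))
        assert not tun.has_cf and np.isnan(tun.cf_hz)

    def test_atypical_fit_filtered(self, grid):
        fits = [None] * 11
        fits[7] = self._make_fit(6300.0, 50.0, rmax=5.0)   # 5x the data max
        p = np.full(11, 1.0)
        p[7] = 0.001
        tun = select_characteristic_frequency(fits, self._fra_stub(grid), p)
        assert not tun.has_cf


class TestBandwidth:
    def test_enumerated_c50_profile(self, grid):
        fits = [None] * 11
        profile = {6: 50.0, 5: 55.0, 7: 58.0, 8: 65.0}
        p = np.full(11, 1.0)
        tc = TestCFSelection()
        for fi, c in profile.items():
            fits[fi] = tc._make_fit(grid.center_frequencies[fi], c)
            p[fi] = 0.001
        tun = select_characteristic_frequency(fits, tc._fra_stub(grid), p)
        assert tun.cf_index == 6
        # cutoff 60 dB: neighbors at 55 and 58 pass, 65 does not -> 3 bands
        assert tuning_bandwidth(tun, fits, tc._fra_stub(grid)) == 3

    def test_single_passing_frequency_gives_one_band(self, grid):
        tc = TestCFSelection()
        fits = [None] * 11
        fits[4] = tc._make_fit(grid.center_frequencies[4], 52.0)
        p = np.full(11, 1.0)
        p[4] = 0.001
        tun = select_characteristic_frequency(fits, tc._fra_stub(grid), p)
        assert tuning_bandwidth(tun, fits, tc._fra_stub(grid)) == 1

    def test_fixed_amplitude_mode_counts_half_max_bands(self, grid):
        f = TestCFSelection()._fra_stub(grid)
        f.rates = np.zeros((11, 8))
        f.rates[:, 4] = [0, 0, 1, 4, 10, 4, 1, 0, 0, 0, 0]
        tun = select_characteristic_frequency([None] * 11, f, np.full(11, 1.0))
        assert tuning_bandwidth(tun, [None] * 11, f, mode="fixed_amplitude",
                                spl_db=f.spls[4]) == 1
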