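import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from chronotell import (
    ClockSimConfig,
    circular_mean_hours,
    circular_sd_hours,
    cosinor_fit,
    leave_one_out,
    pdp_regression,
    precision_without_timestamps,
    signed_circular_error,
    simulate_training,
    theta_stratify_and_resample,
    timing_displacement,
)
from chronotell.cohort import default_de_test


class TestCircularArithmetic:
    @pytest.mark.parametrize(
        "T,Ta,expected",
        [(1.0, 23.0, 2.0), (23.0, 1.0, -2.0), (8.0, 8.0, 0.0), (20.0, 8.0, 12.0)],
    )
    def test_signed_error_wraps_correctly(self, T, Ta, expected):
        assert signed_circular_error(T, Ta) == pytest.approx(expected)

    def test_signed_error_range_is_half_open(self):
        rng = np.random.default_rng(0)
        e = signed_circular_error(rng.uniform(0, 24, 500), rng.uniform(0, 24, 500))
        assert np.all(e > -12.0) and np.all(e <= 12.0)

    def test_antipodal_pair_means_to_boundary(self):
        # errors +11 and -11 average to +12 on the circle, not 0
        assert circular_mean_hours([11.0, -11.0]) == pytest.approx(12.0)

    def test_two_angle_sd_closed_form(self):
        expected = np.sqrt(-2 * np.log(np.cos(np.pi / 12))) * 24 / (2 * np.pi)
        assert circular_sd_hours([-1.0, 1.0]) == pytest.approx(expected)

    def test_low_resultant_mean_undefined(self):
        assert np.isnan(circular_mean_hours([0.0, 12.0], min_resultant=0.1))


class TestCosinor:
    def test_exact_recovery_of_noiseless_cosine(self):
        t = np.arange(0, 24, 3.0)
        y = np.cos(2 * np.pi * (t - 6.0) / 24.0)
        mesor, amp, phi, p = cosinor_fit(t, y)
        assert mesor == pytest.approx(0.0, abs=1e-12)
        assert amp == pytest.approx(1.0, abs=1e-12)
        assert phi == pytest.approx(6.0, abs=1e-10)
        assert p < 1e-12

    def test_constant_series_is_null(self):
        t = np.arange(0, 24, 3.0)
        _, amp, _, p = cosinor_fit(t, np.full_like(t, 2.5))
        assert amp == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_monte_carlo_recovery_within_3_se(self):
        rng = np.random.default_rng(1)
        t = np.arange(24.0)
        y = 2.0 + 0.5 * np.cos(2 * np.pi * (t - 20.0) / 24.0) + rng.normal(0, 0.1, 24)
        mesor, amp, phi, p = cosinor_fit(t, y)
        se = 0.1 / np.sqrt(24)
        assert abs(mesor - 2.0) < 3 * se
        assert abs(amp - 0.5) < 3 * se * np.sqrt(2)
        assert abs(signed_circular_error(phi, 20.0)) < 3 * (0.1 / 0.5) * 24 / (2 * np.pi) / np.sqrt(12)
        assert p < 1e-6

    def test_collinear_design_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            cosinor_fit([0.0, 0.0, 12.0, 12.0], [1.0, 1.1, 2.0, 2.1])

    def test_matches_statsmodels_ols_f_test(self):
        # independent route: explicit OLS fit with harmonic regressors
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 24, 30)
        y = 1.0 + 0.7 * np.cos(2 * np.pi * (t - 9.0) / 24.0) + rng.normal(0, 0.3, 30)
        mesor, amp, phi, p = cosinor_fit(t, y)
        X = sm.add_constant(
            np.column_stack([np.cos(2 * np.pi * t / 24), np.sin(2 * np.pi * t / 24)])
        )
        fit = sm.OLS(y, X).fit()
        assert mesor == pytest.approx(fit.params[0], abs=1e-10)
        assert amp == pytest.approx(np.hypot(fit.params[1], fit.params[2]), abs=1e-10)
        assert p == pytest.approx(fit.f_pvalue, abs=1e-12)


class TestTimingDisplacement:
    def _errors(self, groups, errors, times=None):
        n = len(groups)
        times = times if times is not None else np.full(n, 8.0)
        return pd.DataFrame(
            {
                "sample_id": [f"s{k}" for k in range(n)],
                "instance": groups,
                "time": times,
                "T": (np.asarray(times) + np.asarray(errors)) % 24.0,
                "signed_error": errors,
            }
        )

    def test_constant_errors_fully_corrected(self):
        df = self._errors(["a"] * 3 + ["b"] * 3, [2.0, 2.0, 2.0, 0.0, 0.0, 0.0])
        disp, corrected, _ = timing_displacement(df)
        row = disp.set_index("group").loc["a"]
        assert row["displacement"] == pytest.approx(2.0)
        np.testing.assert_allclose(
            corrected.loc[corrected.instance == "a", "corrected_signed_error"], 0.0, atol=1e-12
        )

    def test_type_i_error_calibrated(self):
        # equal error distributions in two groups: the rank-sum comparison
        # rejects at close to the nominal 5% rate
        rng = np.random.default_rng(3)
        reps, rejections = 400, 0
        for _ in range(reps):
            e = rng.normal(0, 1.0, 24)
            df = self._errors(["a"] * 12 + ["b"] * 12, e)
            _, _, pairwise = timing_displacement(df)
            rejections += pairwise["p"].iloc[0] < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_singleton_group_reported_without_test(self):
        df = self._errors(["a", "b", "b"], [1.0, 0.5, 0.7])
        disp, _, pairwise = timing_displacement(df)
        assert np.isnan(disp.set_index("group").loc["a", "p_vs_rest"])
        assert np.isnan(pairwise["p"].iloc[0])

    def test_rank_sum_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        p1 = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        p2 = stats.mannwhitneyu(np.exp(a), np.exp(b), alternative="two-sided").pvalue
        assert p1 == pytest.approx(p2)


class TestPdpRegression:
    GROUPS = [f"g{k}" for k in range(6)]

    def _phases(self, slope, noise_sd, rng, n_genes=5, base=None):
        disp = pd.Series(np.linspace(-3, 3, 6), index=self.GROUPS)
        base = base if base is not None else rng.uniform(0, 24, n_genes)
        rows = {
            g: (base + slope * d + rng.normal(0, noise_sd, n_genes)) % 24.0
            for g, d in disp.items()
        }
        return pd.DataFrame(rows, index=[f"gene{k}" for k in range(n_genes)]), disp

    def test_perfect_coherence_slope_one(self):
        rng = np.random.default_rng(5)
        phases, disp = self._phases(1.0, 0.0, rng)
        res = pdp_regression(phases, disp)
        np.testing.assert_allclose(res["slope"], 1.0, atol=1e-10)
        np.testing.assert_allclose(res["r2"], 1.0, atol=1e-12)
        assert (res["p_slope"] < 1e-10).all()

    def test_half_slope_recovered_within_ci(self):
        rng = np.random.default_rng(6)
        phases, disp = self._phases(0.5, 0.1, rng)
        res = pdp_regression(phases, disp)
        assert np.all(np.abs(res["slope"] - 0.5) < 0.15)

    def test_wrapping_phases_handled_by_unwrap(self):
        rng = np.random.default_rng(7)
        phases, disp = self._phases(1.0, 0.0, rng, base=np.full(5, 23.0))
        res = pdp_regression(phases, disp)
        np.testing.assert_allclose(res["slope"], 1.0, atol=1e-8)

    def test_needs_three_groups(self):
        phases = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"])
        with pytest.raises(ValueError, match="3 groups"):
            pdp_regression(phases, pd.Series({"a": 0.0, "b": 1.0}))

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(8)
        phases, disp = self._phases(0.8, 0.3, rng, n_genes=1, base=np.array([12.0]))
        res = pdp_regression(phases, disp)
        X = sm.add_constant(disp.to_numpy())
        fit = sm.OLS(phases.iloc[0].to_numpy(), X).fit()
        assert res["slope"].iloc[0] == pytest.approx(fit.params[1], abs=1e-10)
        assert res["r2"].iloc[0] == pytest.approx(fit.rsquared, abs=1e-10)
        assert res["p_slope"].iloc[0] == pytest.approx(fit.f_pvalue, abs=1e-12)


class TestStratification:
    def test_empty_de_test_gives_zero_curves(self):
        rng = np.random.default_rng(9)
        expr = rng.normal(size=(10, 40))
        res = theta_stratify_and_resample(
            lambda lt: rng.uniform(0, 1, 40),
            expr,
            n_range=(5, 8),
            lthresh_range=(-13.0, -11.0),
            de_test=lambda a, b: [],
            iters=20,
            seed=0,
        )
        assert np.all(res.p_rand == 0) and np.all(res.p_theta == 0)

    def test_known_effect_enriches_p_theta_over_p_rand(self):
        # 12 samples with bad clocks (high theta) carry a 6-gene signature
        rng = np.random.default_rng(10)
        n, g = 60, 30
        theta_vals = np.concatenate([np.full(12, 0.8), np.full(48, 0.05)])
        expr = rng.normal(0, 1, size=(g, n))
        expr[:6, :12] += 3.0  # signature genes shifted in the bad-clock group
        res = theta_stratify_and_resample(
            lambda lt: theta_vals,
            expr,
            n_range=(10, 14),
            lthresh_range=(-13.0, -11.0),
            iters=60,
            seed=1,
        )
        m = 5
        assert res.p_theta[m - 1] > 0.9
        assert res.p_rand[m - 1] < 0.2
        assert set(res.bcg_ids) >= set(range(12))
        assert len(set(res.bcg_ids) & set(res.gcg_ids)) == 0

    def test_p_curves_non_increasing_in_m(self):
        rng = np.random.default_rng(11)
        expr = rng.normal(size=(15, 40))
        expr[:3, :8] += 2.0
        res = theta_stratify_and_resample(
            lambda lt: rng.uniform(0, 1, 40),
            expr,
            n_range=(6, 10),
            lthresh_range=(-12.0, -11.0),
            iters=40,
            seed=2,
        )
        assert np.all(np.diff(res.p_rand) <= 0)
        assert np.all(np.diff(res.p_theta) <= 0)

    def test_oversized_group_rejected(self):
        with pytest.raises(ValueError, match="half the cohort"):
            theta_stratify_and_resample(
                lambda lt: np.zeros(10),
                np.zeros((5, 10)),
                n_range=(2, 6),
                lthresh_range=(-12, -11),
                iters=10,
            )

    def test_default_de_test_finds_large_shift(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, size=(8, 15))
        b = rng.normal(0, 1, size=(8, 15))
        b[2] += 4.0
        hits = default_de_test(a, b)
        assert 2 in hits and len(hits) <= 3


class TestPrecision:
    def test_noiseless_monotone_curve_has_tiny_sd(self):
        rng = np.random.default_rng(13)
        T = rng.uniform(12, 16, 60)
        g = 2.0 * T  # strictly monotone, no noise
        revs = np.outer(np.array([1.0, 2.0, -1.0]) / np.sqrt(6), g)
        sd, dev = precision_without_timestamps(revs, T, (12, 16))
        assert sd < 4.0 / 480  # window grid resolution

    def test_linear_model_oracle_within_15_percent(self):
        rng = np.random.default_rng(14)
        n, a, sigma = 200, 1.0, 0.5
        T = rng.uniform(10, 18, n)
        g = a * T + rng.normal(0, sigma, n)
        revs = np.outer(np.array([3.0, 4.0, 1.0]) / np.sqrt(26), g)
        sd, dev = precision_without_timestamps(revs, T, (10, 18))
        assert abs(sd - sigma / a) / (sigma / a) < 0.15
        assert len(dev) == n

    def test_too_few_samples_rejected(self):
        T = np.linspace(12, 16, 20)
        revs = np.outer([1.0, 1.0], T)
        with pytest.raises(ValueError, match="at least 30"):
            precision_without_timestamps(revs, T, (12, 16))

    def test_non_monotone_curve_rejected(self):
        rng = np.random.default_rng(15)
        T = rng.uniform(0, 24, 100)
        g = np.sin(2 * np.pi * T / 24.0)  # two monotone branches over a day
        revs = np.outer([1.0, 0.5], g)
        with pytest.raises(ValueError, match="non-monotone"):
            precision_without_timestamps(revs, T, (0, 23.9))


class TestLeaveOneOut:
    def test_instance_unit_recovers_injected_chronotype(self, bundle_es):
        loo = leave_one_out(bundle_es, unit="instance")
        disp, corrected, _ = timing_displacement(loo)
        d = disp.set_index("group").loc["inst03", "displacement"]
        assert 1.5 < d < 2.5

    def test_zero_noise_errors_below_grid_resolution(self):
        es = simulate_training(ClockSimConfig(noise_sd=0.0, factor_sd=0.0, seed=20))
        loo = leave_one_out(es)
        assert loo["abs_error"].max() <= 24.0 / 1440

    def test_unknown_unit_rejected(self, bundle_es):
        with pytest.raises(ValueError, match="unit"):
            leave_one_out(bundle_es, unit="gene")
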