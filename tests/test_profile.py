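import numpy as np
import pytest

from chronotell import (
    LikelihoodProfile,
    ThetaConfig,
    adjust_time_by_second_peak,
    build_profile,
    choose_lthresh,
    classify_dysfunction,
    combine_loglik,
    estimate_phase,
    find_peaks,
    reference_curve,
    theta,
)

GRID = np.arange(1440) * (24.0 / 1440)
CFG = ThetaConfig()


def _profile_from_curve(log_l_curve, l_thresh=-5.0):
    return build_profile(log_l_curve[None, :], GRID, l_thresh, CFG)


class TestThetaConfig:
    def test_default_satisfies_constraint(self):
        c = ThetaConfig()
        assert 0 < c.eta * c.eps < c.eta * (2 + c.eps) < 1

    @pytest.mark.parametrize("eta,eps", [(0.5, 1.2), (0.6, 0.0), (-0.1, 0.5)])
    def test_invalid_configs_rejected(self, eta, eps):
        with pytest.raises(ValueError, match="eta"):
            ThetaConfig(eta=eta, eps=eps)


class TestCombine:
    def test_single_curve_above_threshold_is_identity(self):
        c = -2.0 + np.cos(2 * np.pi * GRID / 24)
        np.testing.assert_array_equal(combine_loglik(c[None], -5.0), c)

    def test_all_below_threshold_gives_flat_floor(self):
        c = np.full((3, len(GRID)), -50.0)
        np.testing.assert_array_equal(combine_loglik(c, -5.0), np.full(len(GRID), -5.0))

    def test_hand_computed_mixed_truncation(self):
        c = np.array([[-2.0], [-10.0]])
        assert combine_loglik(c, -5.0)[0] == pytest.approx(-3.5, abs=1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no per-timepoint"):
            combine_loglik(np.empty((0, 10)), -5.0)


class TestEstimatePhase:
    def test_unique_maximum(self):
        c = -((GRID - 13.0) ** 2)
        T, ml, flags = estimate_phase(c, GRID)
        assert T == 13.0 and not flags

    def test_flat_curve_tie_rule(self):
        T, _, flags = estimate_phase(np.zeros(len(GRID)), GRID)
        assert T == 0.0 and "flat_curve" in flags

    def test_two_equal_maxima_earliest_wins(self):
        c = np.full(len(GRID), -10.0)
        c[int(4 / 24 * 1440)] = -1.0
        c[int(16 / 24 * 1440)] = -1.0
        T, _, flags = estimate_phase(c, GRID)
        assert T == 4.0 and "multimodal" in flags


class TestTheta:
    def test_flat_at_max_gives_one(self):
        lrf = np.ones(len(GRID))
        assert theta(lrf, 0.0, CFG, GRID) == 1.0

    def test_single_spike_gives_one_grid_point(self):
        lrf = np.full(len(GRID), 0.01)  # below min C = eta*eps = 0.0525
        lrf[600] = 1.0
        assert theta(lrf, GRID[600], CFG, GRID) == pytest.approx(1.0 / 1440)

    def test_scaled_shifted_reference_matches_brute_force(self):
        T_prime, eta_prime = 5.0, 0.45
        lrf = eta_prime * (1 + CFG.eps + np.cos(2 * np.pi * (GRID - T_prime) / 24))
        lrf = lrf / lrf.max()
        T = GRID[np.argmax(lrf)]
        expected = np.mean(lrf > reference_curve(GRID, T, CFG))
        assert theta(lrf, T, CFG, GRID) == pytest.approx(expected)

    def test_exact_equality_does_not_count(self):
        T = 12.0
        lrf = reference_curve(GRID, T, CFG)
        lrf = lrf / 1.0  # max C < 1; equality everywhere below max
        assert theta(lrf, T, CFG, GRID) == 0.0


class TestPeaks:
    def _bimodal(self, h2=0.8, t1=3.0, t2=15.0):
        lrf = np.exp(-0.5 * (((GRID - t1 + 12) % 24 - 12) / 1.0) ** 2)
        lrf += h2 * np.exp(-0.5 * (((GRID - t2 + 12) % 24 - 12) / 1.0) ** 2)
        return lrf / lrf.max()

    def test_unimodal_has_no_second_peak(self):
        lrf = self._bimodal(h2=0.0)
        peaks = find_peaks(lrf, GRID, CFG)
        assert len(peaks) == 1
        assert peaks[0].time == pytest.approx(3.0, abs=0.1)

    def test_bimodal_second_peak_found(self):
        peaks = find_peaks(self._bimodal(), GRID, CFG)
        assert len(peaks) == 2
        assert peaks[0].height > peaks[1].height
        assert peaks[1].time == pytest.approx(15.0, abs=0.1)

    def test_seam_spanning_peak_detected_once(self):
        lrf = np.exp(-0.5 * (((GRID + 12) % 24 - 12) / 1.5) ** 2)  # peak at 0/24
        peaks = find_peaks(lrf / lrf.max(), GRID, CFG)
        assert len(peaks) == 1
        t = peaks[0].time
        assert min(t, 24 - t) < 0.1

    def test_sub_reference_bumps_filtered(self):
        lrf = self._bimodal(h2=0.03)  # second bump below C at its location
        peaks = find_peaks(lrf, GRID, CFG)
        assert len(peaks) == 1


class TestSecondPeakAdjustment:
    def _profile_with_peaks(self, T, second=None):
        from chronotell.profile import Peak

        peaks = [Peak(T, 1.0, 1.0)]
        if second is not None:
            peaks.append(Peak(second, 0.8, 0.5))
        return LikelihoodProfile(
            grid_times=GRID, log_l=np.zeros(1), t=T, ml=1.0, log_ml=0.0,
            lrf=np.ones(1), theta=0.1, peaks=peaks, flat_fraction=0.0,
        )

    def test_in_window_with_second_peak_moves(self):
        p = self._profile_with_peaks(3.0, second=13.5)
        assert adjust_time_by_second_peak(p, (0.0, 7.0)) == 13.5
        assert "second_peak_adjusted" in p.flags

    def test_outside_window_unchanged(self):
        p = self._profile_with_peaks(13.0, second=3.0)
        assert adjust_time_by_second_peak(p, (0.0, 7.0)) == 13.0

    def test_in_window_without_second_peak_flagged(self):
        p = self._profile_with_peaks(3.0)
        assert adjust_time_by_second_peak(p, (0.0, 7.0)) == 3.0
        assert "no_second_peak" in p.flags


class TestChooseLthresh:
    def _training_profiles(self, l_thresh, log_peak=-3.0):
        # well-peaked training curve: sharp Gaussian bump on a low baseline
        base = np.full(len(GRID), -30.0)
        curve = np.maximum(
            base, log_peak - 0.5 * (((GRID - 12 + 12) % 24 - 12) / 0.8) ** 2 * 1.0
        )
        return [_profile_from_curve(curve, l_thresh) for _ in range(10)]

    def test_two_candidate_scenario_selects_larger(self):
        candidates = [-8.0, -4.0]
        train = {c: self._training_profiles(c, log_peak=-1.0) for c in candidates}
        test_mls = {c: np.full(20, -3.0) for c in candidates}
        rec, table = choose_lthresh(train, test_mls, candidates)
        assert rec == -4.0
        assert set(table["l_thresh"]) == set(candidates)

    def test_infeasible_tests_fall_back_with_table(self):
        candidates = [-6.0, -4.0]
        train = {c: self._training_profiles(c) for c in candidates}
        test_mls = {c: np.full(20, -20.0) for c in candidates}  # below all
        rec, table = choose_lthresh(train, test_mls, candidates)
        assert rec in candidates
        assert not table["ok_ml"].any()

    def test_ml_distribution_near_e_minus_4_recommends_minus_5(self):
        # cohort whose smallest log-MLs sit around -4: the recommended floor
        # is the largest candidate still below the bulk of the MLs
        candidates = [-7.0, -6.0, -5.0, -4.0, -3.0]
        train = {c: self._training_profiles(c, log_peak=-2.0) for c in candidates}
        rng = np.random.default_rng(0)
        mls = rng.uniform(-4.0, -1.0, size=200)  # smallest MLs around e^-4
        test_mls = {c: mls for c in candidates}
        rec, _ = choose_lthresh(train, test_mls, candidates)
        assert rec == -5.0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            choose_lthresh({}, {}, [])


class TestClassifyDysfunction:
    SUMMARY = {"ml": np.linspace(0.5, 2.0, 100), "theta": np.linspace(0.01, 0.2, 100)}

    def _sharp_profile(self, T=12.0, log_peak=0.5):
        curve = log_peak - 8.0 * (((GRID - T + 12) % 24 - 12)) ** 2
        return _profile_from_curve(curve)

    def test_training_like_profile_unflagged(self):
        p = self._sharp_profile()
        flags = classify_dysfunction(p, self.SUMMARY, true_time=12.0)
        assert flags == set()

    def test_low_ml_flagged(self):
        p = self._sharp_profile(log_peak=-4.0)
        flags = classify_dysfunction(p, self.SUMMARY, true_time=12.0)
        assert "lowML" in flags

    def test_rel_t_wrong_needs_confident_wrong_time(self):
        p = self._sharp_profile(T=12.0, log_peak=0.5)
        flags = classify_dysfunction(p, self.SUMMARY, true_time=2.0)
        assert "relTwrong" in flags

    def test_missing_true_time_skips_with_notice(self):
        p = self._sharp_profile()
        flags = classify_dysfunction(p, self.SUMMARY, true_time=None)
        assert "relTwrong_skipped_no_true_time" in flags

    def test_broad_profile_is_high_t_var(self):
        curve = 0.5 - 0.02 * (((GRID - 12 + 12) % 24 - 12)) ** 2  # very wide
        p = _profile_from_curve(curve)
        flags = classify_dysfunction(p, self.SUMMARY, true_time=12.0)
        assert "highTvar" in flags
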