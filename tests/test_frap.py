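"""FRAP pipeline: bias correction, ROIs, normalization, fitting, cohorts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmquant.frap import (build_bleach_rois, cohort_curve, correct_bias,
                          extract_series, fit_recovery, normalize_trace)
from pmquant.imgcore import ChannelImage, TimeSeriesStack
from pmquant.synthgen import FrapSimParams, generate_frap_series


def _stack(values, bleach=None):
    frames = [ChannelImage(np.full((8, 8), float(v))) for v in values]
    return TimeSeriesStack(frames, np.arange(len(values), dtype=float), bleach)


class TestCorrectBias:
    def test_constant_bias_subtracted(self):
        stack = _stack([350.0] * 3)
        bg = _stack([100.0] * 100)
        out = correct_bias(stack, bg)
        assert np.all(out.as_array() == 250.0)

    def test_signal_equal_to_bias_gives_zero(self):
        out = correct_bias(_stack([100.0] * 3), _stack([100.0] * 100))
        assert np.all(out.as_array() == 0.0)

    def test_fewer_background_frames_warns(self):
        with pytest.warns(UserWarning, match="background frames"):
            correct_bias(_stack([10.0] * 3), _stack([5.0] * 20))

    def test_idempotent_with_zero_second_bias(self):
        stack = _stack([300.0, 320.0, 310.0])
        bg = _stack([90.0] * 100)
        once = correct_bias(stack, bg)
        zero_bg = _stack([0.0] * 100)
        twice = correct_bias(once, zero_bg)
        np.testing.assert_array_equal(once.as_array(), twice.as_array())

    def test_removes_bias_level_and_gradient(self):
        p = FrapSimParams(noise_sd=0.0, bias_level=120.0, bias_gradient=2.0,
                          seed=0)
        stack, truth = generate_frap_series(p)
        p0 = FrapSimParams(noise_sd=0.0, bias_level=0.0, bias_gradient=0.0,
                           seed=0)
        clean_stack, _ = generate_frap_series(p0)
        corrected = correct_bias(stack, truth.background_stack)
        np.testing.assert_allclose(corrected.as_array(),
                                   clean_stack.as_array(), atol=1e-9)


class TestBuildBleachRois:
    def test_interior_point_is_5x5(self):
        rois = build_bleach_rois([(10, 12)], (32, 32))
        assert rois[0].sum() == 25

    def test_corner_point_cropped_to_9(self):
        rois = build_bleach_rois([(0, 0)], (32, 32))
        assert rois[0].sum() == 9

    def test_duplicates_merged_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            rois = build_bleach_rois([(5, 5), (5, 5)], (32, 32))
        assert len(rois) == 1

    def test_close_points_kept_separate(self):
        rois = build_bleach_rois([(10, 10), (12, 10)], (32, 32))
        assert len(rois) == 2
        assert (rois[0] & rois[1]).sum() > 0      # overlap preserved


class TestNormalizeTrace:
    def test_roi_equal_to_reference_is_unity(self, rng):
        ref = rng.uniform(500, 1000, 40)
        np.testing.assert_allclose(normalize_trace(ref, ref, 10), 1.0)

    def test_constant_multiple_of_reference_is_unity(self, rng):
        ref = rng.uniform(500, 1000, 40)
        np.testing.assert_allclose(normalize_trace(0.37 * ref, ref, 10), 1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_prebleach_mean_is_one(self, seed):
        r = np.random.default_rng(seed)
        roi = r.uniform(10, 1000, 30)
        ref = r.uniform(10, 1000, 30)
        norm = normalize_trace(roi, ref, 8)
        assert norm[:8].mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError, match="strictly positive"):
            normalize_trace(np.ones(10), np.zeros(10), 3)

    def test_incidental_decay_removed_for_immobile_roi(self):
        p = FrapSimParams(mobile_fraction_true=0.0, incidental_rate=0.02,
                          noise_sd=0.0, seed=0)
        stack, truth = generate_frap_series(p)
        corrected = correct_bias(stack, truth.background_stack)
        rois = build_bleach_rois([truth.bleach_point], stack.frames[0].shape)
        series = extract_series(corrected, rois)
        norm = normalize_trace(series.roi_traces["roi0"],
                               series.reference_trace,
                               series.bleach_frame_index)
        post = norm[p.pre_frames:]
        assert np.ptp(post) / post.mean() < 0.02


class TestFitRecovery:
    def _trace(self, f_post, f_inf, k=0.3, n_pre=5, n_post=60, dt=0.5):
        t = dt * np.arange(n_pre + n_post)
        y = np.ones(n_pre + n_post)
        post_t = t[n_pre:] - t[n_pre]
        y[n_pre:] = f_inf - (f_inf - f_post) * np.exp(-k * post_t)
        return y, t, n_pre

    def test_noiseless_trace_hand_value(self):
        y, t, b = self._trace(0.2, 0.36)
        fit = fit_recovery(y, t, b)
        assert fit.mobile_fraction == pytest.approx(0.2, abs=1e-6)
        assert fit.immobile_fraction == pytest.approx(0.8, abs=1e-6)

    def test_constant_post_bleach_is_immobile(self):
        y, t, b = self._trace(0.25, 0.25)
        fit = fit_recovery(y, t, b)
        assert fit.mobile_fraction == pytest.approx(0.0, abs=1e-6)

    def test_endpoint_mode_cross_checks_fit(self):
        y, t, b = self._trace(0.2, 0.36, k=0.5)
        fit = fit_recovery(y, t, b, mode="fit")
        end = fit_recovery(y, t, b, mode="endpoint")
        assert abs(fit.mobile_fraction - end.mobile_fraction) < 0.02

    def test_fitted_model_monotone_post_bleach(self):
        y, t, b = self._trace(0.3, 0.7, k=0.2)
        fit = fit_recovery(y, t, b)
        post_t = np.linspace(0, 30, 100)
        model = fit.F_inf - (fit.F_inf - fit.F_post) * np.exp(-fit.k * post_t)
        assert np.all(np.diff(model) >= -1e-12)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match="3 post-bleach"):
            fit_recovery(np.ones(6), np.arange(6.0), 4)

    @pytest.mark.parametrize("truth,k_dt", [(0.0, 0.1), (0.2, 0.05),
                                            (0.35, 0.2), (1.0, 0.5)])
    def test_parameter_recovery_at_five_percent_noise(self, truth, k_dt):
        mobiles = []
        for seed in range(20):
            p = FrapSimParams(mobile_fraction_true=truth,
                              rate_k=k_dt / 0.5, frame_interval=0.5,
                              noise_sd=50.0, seed=seed)
            stack, tr = generate_frap_series(p)
            corrected = correct_bias(stack, tr.background_stack)
            rois = build_bleach_rois([tr.bleach_point], stack.frames[0].shape)
            series = extract_series(corrected, rois)
            norm = normalize_trace(series.roi_traces["roi0"],
                                   series.reference_trace,
                                   series.bleach_frame_index)
            fit = fit_recovery(norm, series.timestamps,
                               series.bleach_frame_index)
            if fit.valid:
                mobiles.append(fit.mobile_fraction)
        assert len(mobiles) >= 18
        assert abs(np.mean(mobiles) - truth) < 0.05


class TestCohortCurve:
    def test_identical_traces_zero_sd(self):
        t = np.linspace(0, 1, 20)
        out = cohort_curve([t, t.copy(), t.copy()])
        np.testing.assert_allclose(out["sd_trace"], 0.0, atol=1e-12)

    def test_constant_offset_sd(self):
        t = np.linspace(0, 1, 20)
        d = 0.3
        out = cohort_curve([t, t + 2 * d])
        np.testing.assert_allclose(out["sd_trace"], d * np.sqrt(2.0))

    def test_needs_two_traces(self):
        with pytest.raises(ValueError, match="two traces"):
            cohort_curve([np.ones(5)])
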