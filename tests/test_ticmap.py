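"""TIC landmark detection and wash-in gradient mapping."""

import numpy as np
import pytest

from ceustic import (
    BolusModel,
    PhantomSpec,
    TicConfig,
    ValidationError,
    analytic_mean_gradient,
    analytic_start_time,
    compute_map,
    detect_landmarks,
    extract_tic,
    gamma_variate,
    make_phantom,
    mean_gradient_to_peak,
    moving_average,
)
from ceustic.ticmap import (
    QUALITY_CENSORED_PEAK,
    QUALITY_NO_ENHANCEMENT,
    QUALITY_OK,
    colorize,
)


class TestMovingAverage:
    def test_constant_trace_unchanged(self):
        y = np.full(20, 3.0)
        assert np.array_equal(moving_average(y, 5), y)

    def test_window_one_is_identity(self):
        y = np.arange(10.0)
        assert np.array_equal(moving_average(y, 1), y)

    def test_truncated_edges_match_direct_mean(self):
        rng = np.random.default_rng(0)
        y = rng.random(15)
        out = moving_average(y, 5)
        direct = np.array([y[max(0, i - 2): i + 3].mean() for i in range(15)])
        assert np.allclose(out, direct)


class TestLandmarks:
    def test_piecewise_linear_ramp_closed_form(self):
        # flat 0 until t=2, ramp to 10 over 5 s, then constant; with a 10%
        # threshold the closed form gives t_start = 2.5 and t_peak = 7
        t = np.arange(0.0, 12.0, 0.01)
        y = np.clip(2.0 * (t - 2.0), 0.0, 10.0)
        c = detect_landmarks(y, t, threshold_frac=0.1, smooth_window=1)
        assert c.quality == QUALITY_OK
        assert c.baseline == pytest.approx(0.0, abs=1e-12)
        assert c.t_start == pytest.approx(2.5, abs=0.01)
        assert c.t_peak == pytest.approx(7.0, abs=0.01)
        assert c.y_peak == pytest.approx(10.0)

    def test_constant_trace_flags_no_enhancement(self):
        t = np.arange(10.0)
        c = detect_landmarks(np.full(10, 4.0), t)
        assert c.quality == QUALITY_NO_ENHANCEMENT
        assert c.baseline == pytest.approx(4.0)

    def test_peak_on_final_frame_is_censored(self):
        t = np.arange(20.0)
        c = detect_landmarks(t.copy(), t, smooth_window=1)  # still rising at the end
        assert c.quality == QUALITY_CENSORED_PEAK

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="4 samples"):
            detect_landmarks(np.ones(3), np.arange(3.0))

    def test_gamma_variate_start_time_matches_root_oracle(self):
        # closed-form oracle: root-bracket the exact curve at baseline + 5% ymax
        m = BolusModel(t0=5, tpk=15, ymax=20, alpha=2, baseline=1)
        dt = 0.25
        t = np.arange(0, 120, dt)
        c = detect_landmarks(gamma_variate(t, m), t, threshold_frac=0.05, smooth_window=1)
        assert abs(c.t_start - analytic_start_time(m, 0.05)) <= dt
        assert abs(c.t_peak - 15.0) <= dt

    def test_phantom_pixel_landmarks(self):
        m = BolusModel(t0=5, tpk=15, ymax=20, alpha=1.5, baseline=1)
        t = np.arange(0, 120, 0.5)
        c = detect_landmarks(gamma_variate(t, m), t, smooth_window=5)
        assert abs(c.t_peak - 15.0) <= 0.5
        assert abs(c.t_start - 5.0) <= 1.0

    def test_smoothing_keeps_peak_within_half_window(self):
        m = BolusModel(t0=5, tpk=15, ymax=20, alpha=1.5, baseline=1)
        t = np.arange(0, 120, 0.5)
        y = gamma_variate(t, m)
        base = detect_landmarks(y, t, smooth_window=1).t_peak
        for w in (3, 5, 7, 9):
            moved = abs(detect_landmarks(y, t, smooth_window=w).t_peak - base)
            assert moved <= (w // 2) * 0.5 + 1e-9


class TestGradient:
    def test_linear_ramp_constant_slope(self):
        t = np.arange(0.0, 8.0, 0.05)
        y = np.clip(2.0 * t, 0.0, 10.0)
        c = detect_landmarks(y, t, threshold_frac=0.01, smooth_window=1)
        assert mean_gradient_to_peak(c) == pytest.approx(2.0, rel=0.02)

    def test_no_enhancement_pixel_raises(self):
        c = detect_landmarks(np.full(10, 4.0), np.arange(10.0))
        with pytest.raises(ValidationError, match="no enhancement"):
            mean_gradient_to_peak(c)

    def test_closed_form_oracle_value(self):
        m = BolusModel(t0=5, tpk=15, ymax=20, alpha=2, baseline=1)
        t = np.arange(0, 120, 0.25)
        c = detect_landmarks(gamma_variate(t, m), t, threshold_frac=0.05, smooth_window=1)
        oracle = analytic_mean_gradient(m, 0.05)
        assert mean_gradient_to_peak(c) == pytest.approx(oracle, rel=0.02)
        # as the threshold goes to zero the quotient approaches ymax/(tpk-t0)
        assert analytic_mean_gradient(m, 1e-6) == pytest.approx(2.0, rel=0.01)


class TestComputeMap:
    def test_homogeneous_phantom_constant_map(self, small_phantom):
        loop, roi, gt = small_phantom
        pmap = compute_map(loop, roi)
        ok = pmap.ok_values()
        assert ok.size > 0
        assert ok.std() / ok.mean() < 1e-6
        assert ok.mean() == pytest.approx(gt.background.mean_gradient, rel=0.05)

    def test_outside_mask_never_numeric(self, small_phantom):
        loop, roi, _ = small_phantom
        pmap = compute_map(loop, roi)
        assert np.all(np.isnan(pmap.values[~roi.mask]))
        ok = (pmap.quality == QUALITY_OK) & roi.mask
        assert np.all(np.isfinite(pmap.values[ok]))
        assert np.all(np.isnan(pmap.values[~ok]))

    def test_lesion_background_ratio_matches_kinetics(self, type1_phantom):
        loop, roi, gt = type1_phantom
        pmap = compute_map(loop, roi)
        sel_ok = pmap.quality == QUALITY_OK
        inside = pmap.values[(gt.label_image > 0) & sel_ok].mean()
        outside = pmap.values[(gt.label_image == 0) & roi.mask & sel_ok].mean()
        assert inside / outside == pytest.approx(4.0, rel=0.10)

    def test_scale_equivariance_exact(self, small_phantom):
        loop, roi, _ = small_phantom
        a = compute_map(loop, roi)
        scaled = loop.copy()
        scaled.frames *= 3.0
        b = compute_map(scaled, roi, config=TicConfig(noise_floor=3e-6))
        sel = (a.quality == QUALITY_OK) & roi.mask
        assert np.array_equal(b.values[sel], 3.0 * a.values[sel])

    def test_time_shift_invariance(self, small_phantom):
        loop, roi, _ = small_phantom
        a = compute_map(loop, roi)
        shifted = loop.copy()
        shifted.times = loop.times + 7.5
        b = compute_map(shifted, roi)
        sel = (a.quality == QUALITY_OK) & roi.mask
        assert np.allclose(a.values[sel], b.values[sel])

    def test_determinism(self, type1_phantom):
        loop, roi, _ = type1_phantom
        a = compute_map(loop, roi)
        b = compute_map(loop, roi)
        assert np.array_equal(a.values, b.values, equal_nan=True)
        assert np.array_equal(a.quality, b.quality)

    def test_extract_tic_out_of_bounds(self, small_phantom):
        loop, _, _ = small_phantom
        with pytest.raises(ValidationError, match="outside frame bounds"):
            extract_tic(loop, 999, 0)

    def test_map_save_load_round_trip(self, small_phantom, tmp_path):
        loop, roi, _ = small_phantom
        pmap = compute_map(loop, roi)
        back = type(pmap).load(pmap.save(tmp_path / "map.npz"))
        assert np.array_equal(back.values, pmap.values, equal_nan=True)
        assert back.parameter_name == pmap.parameter_name


class TestRendering:
    def test_two_valued_map_hits_colormap_endpoints(self, small_phantom):
        loop, roi, _ = small_phantom
        pmap = compute_map(loop, roi)
        vals = pmap.values.copy()
        rr, cc = np.nonzero(roi.mask & (pmap.quality == QUALITY_OK))
        half = len(rr) // 2
        vals[rr[:half], cc[:half]] = 1.0
        vals[rr[half:], cc[half:]] = 2.0
        pmap.values = vals
        rgb = colorize(pmap, colormap="jet")
        import matplotlib
        cmap = matplotlib.colormaps["jet"]
        cold = (np.asarray(cmap(0.0))[:3] * 255).astype(np.uint8)
        hot = (np.asarray(cmap(1.0))[:3] * 255).astype(np.uint8)
        assert np.array_equal(rgb[rr[0], cc[0]], cold)
        assert np.array_equal(rgb[rr[-1], cc[-1]], hot)

    def test_constant_map_single_colour(self, small_phantom):
        loop, roi, _ = small_phantom
        pmap = compute_map(loop, roi)
        rgb = colorize(pmap)
        in_mask = rgb[roi.mask & (pmap.quality == QUALITY_OK)]
        assert np.unique(in_mask, axis=0).shape[0] == 1

    def test_render_writes_png(self, small_phantom, tmp_path):
        from ceustic import render_map
        loop, roi, _ = small_phantom
        pmap = compute_map(loop, roi)
        out = render_map(pmap, out=tmp_path / "map.png", reference=loop.frames[-1])
        assert out.exists() and out.stat().st_size > 0
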