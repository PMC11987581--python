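"""STICS engine: tiling, correlation (vs direct-sum oracle), peak fitting,
tracking, velocity regression and the assembled analyze pipeline."""

import numpy as np
import pytest

from sticsflow import (
    ImageSeries,
    SticsParams,
    analyze,
    correlation_function,
    fit_gaussian_peak,
    subtract_immobile,
    tile_rois,
    track_peaks,
    velocity_from_peaks,
)
from sticsflow.stics import CorrelationFunction, _taper_window


# ---------------------------------------------------------------- oracles

def direct_sum_correlation(stack, max_lag, taper="none", normalize=True):
    """O(N⁴) nested-sum spatiotemporal correlation (independent oracle).

    Same estimator definition as the FFT path: cyclic cross-correlation of
    per-frame spatial-mean-subtracted fluctuations, averaged over frame
    pairs, overlap-normalized (Hann autocorrelation with a 1e-3 floor when
    tapered, pixel count otherwise), optionally divided by the pair of
    spatial means.
    """
    stack = np.asarray(stack, dtype=float)
    n_t, rows, cols = stack.shape
    means = stack.mean(axis=(1, 2))
    delta = stack - means[:, None, None]
    if taper == "hann":
        w = np.outer(np.hanning(rows), np.hanning(cols))
        delta = delta * w
        overlap = np.zeros((rows, cols))
        for dr in range(rows):
            for dc in range(cols):
                s = 0.0
                for y in range(rows):
                    for x in range(cols):
                        s += w[y, x] * w[(y + dr) % rows, (x + dc) % cols]
                overlap[dr, dc] = s
        overlap = np.maximum(overlap, 1e-3 * overlap.max())
    else:
        overlap = np.full((rows, cols), float(rows * cols))

    guard = 1e-9 * max(np.abs(stack).max(), np.finfo(float).tiny)
    use_norm = normalize and bool(np.all(means > guard))
    out = np.empty((max_lag + 1, rows, cols))
    for tau in range(max_lag + 1):
        acc = np.zeros((rows, cols))
        for t in range(n_t - tau):
            c = np.zeros((rows, cols))
            for dr in range(rows):
                for dc in range(cols):
                    s = 0.0
                    for y in range(rows):
                        for x in range(cols):
                            s += (delta[t, y, x]
                                  * delta[t + tau, (y + dr) % rows, (x + dc) % cols])
                    c[dr, dc] = s
            c = c / overlap
            if use_norm:
                c = c / (means[t] * means[t + tau])
            acc += c
        out[tau] = np.fft.fftshift(acc / (n_t - tau))
    return out


def translating_spot_stack(n_frames=5, size=32, step=1):
    """Gaussian spot cyclically rolled `step` px rightward per frame."""
    yy, xx = np.mgrid[0:size, 0:size]
    spot = np.exp(-(((xx - size // 2) ** 2 + (yy - size // 2) ** 2) / (2 * 2.0**2)))
    return np.stack([np.roll(spot, t * step, axis=1) for t in range(n_frames)])


# ---------------------------------------------------------------- tiling

class TestTileRois:
    def test_reference_tiling_yields_324_rois(self):
        origins = tile_rois((100, 100), 32, 4)
        assert len(origins) == 324  # 18 positions per axis
        assert origins[0] == (0, 0) and origins[-1] == (68, 68)

    def test_single_roi_when_roi_fills_frame(self):
        assert tile_rois((32, 32), 32, 4) == [(0, 0)]

    def test_small_roi_fine_shift(self):
        origins = tile_rois((100, 100), 16, 2)
        assert len(origins) == 43 * 43

    def test_row_major_order(self):
        origins = tile_rois((20, 20), 10, 5)
        assert origins == [(0, 0), (0, 5), (0, 10), (5, 0), (5, 5), (5, 10),
                           (10, 0), (10, 5), (10, 10)]

    def test_oversized_roi_rejected(self):
        with pytest.raises(ValueError):
            tile_rois((20, 20), 32, 4)


class TestSubtractImmobile:
    def test_static_stack_maps_to_zero(self):
        stack = np.tile(np.random.default_rng(0).uniform(size=(1, 6, 6)), (5, 1, 1))
        np.testing.assert_allclose(subtract_immobile(stack), 0.0, atol=1e-15)

    def test_per_pixel_temporal_mean_is_zero(self, rng):
        out = subtract_immobile(rng.uniform(size=(7, 8, 8)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_linear_trace_centered(self):
        stack = np.arange(1.0, 6.0)[:, None, None] * np.ones((1, 1))
        np.testing.assert_allclose(
            subtract_immobile(stack)[:, 0, 0], [-2, -1, 0, 1, 2]
        )


class TestCorrelationFunction:
    def test_identical_frames_after_immobile_subtraction_are_silent(self, rng):
        stack = np.tile(rng.uniform(1, 5, size=(1, 8, 8)), (4, 1, 1))
        corr = correlation_function(subtract_immobile(stack), max_lag=2)
        np.testing.assert_allclose(corr.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("taper", ["none", "hann"])
    def test_translating_spot_peaks_at_the_displacement(self, taper):
        stack = translating_spot_stack()
        corr = correlation_function(stack, max_lag=3, taper=taper)
        c = corr.center
        for tau in range(1, 4):
            peak = np.unravel_index(np.argmax(corr.values[tau]),
                                    corr.values[tau].shape)
            assert peak == (c[0], c[1] + tau), f"tau={tau}"

    @pytest.mark.parametrize("taper", ["none", "hann"])
    def test_fft_path_equals_direct_sum_oracle(self, rng, taper):
        stack = rng.uniform(0.5, 2.0, size=(4, 8, 8))
        corr = correlation_function(stack, max_lag=3, taper=taper)
        oracle = direct_sum_correlation(stack, max_lag=3, taper=taper)
        np.testing.assert_allclose(corr.values, oracle, rtol=1e-10, atol=1e-13)

    def test_zero_lag_slice_is_point_symmetric(self, rng):
        stack = rng.uniform(0, 3, size=(4, 12, 12))
        v0 = correlation_function(stack, max_lag=1).values[0]
        # r(ξ, η, 0) = r(−ξ, −η, 0): flip about the center
        flipped = np.roll(np.flip(v0), (1, 1), axis=(0, 1))  # even-size center fix
        np.testing.assert_allclose(v0, flipped, rtol=1e-9, atol=1e-12)

    def test_normalization_guard_on_mean_subtracted_data(self, rng):
        stack = subtract_immobile(rng.uniform(1, 5, size=(4, 8, 8)))
        corr = correlation_function(stack, max_lag=2, normalize=True)
        assert corr.normalization_used == [False, False, False]
        raw = rng.uniform(1, 5, size=(4, 8, 8))
        corr = correlation_function(raw, max_lag=2, normalize=True)
        assert corr.normalization_used == [True, True, True]

    def test_all_zero_stack_flagged_empty(self):
        corr = correlation_function(np.zeros((4, 8, 8)), max_lag=2)
        assert corr.empty

    def test_max_lag_validation(self, rng):
        with pytest.raises(ValueError):
            correlation_function(rng.uniform(size=(3, 8, 8)), max_lag=3)


class TestFitGaussianPeak:
    def test_noiseless_gaussian_recovered_exactly(self):
        yy, xx = np.mgrid[0:33, 0:33]
        slice_ = 0.7 * np.exp(
            -(((xx - 16) - 1.3) ** 2 + ((yy - 16) + 0.7) ** 2) / 3.0**2
        ) + 0.1
        fit = fit_gaussian_peak(slice_, init_center=(0, 0), search_radius=8)
        assert fit.converged
        np.testing.assert_allclose(fit.center, (1.3, -0.7), atol=1e-6)
        assert abs(fit.width - 3.0) < 1e-6
        assert abs(fit.amplitude - 0.7) < 1e-6
        assert abs(fit.offset - 0.1) < 1e-6

    def test_constant_slice_fails(self):
        fit = fit_gaussian_peak(np.ones((17, 17)), (0, 0), 4)
        assert not fit.converged

    def test_gaussian_on_ramp_center_within_two_tenths_px(self):
        yy, xx = np.mgrid[0:33, 0:33]
        truth = (0.9 * np.exp(-(((xx - 16) - 2.0) ** 2 + (yy - 16) ** 2) / 2.5**2)
                 + 0.01 * xx)
        fit = fit_gaussian_peak(truth, (0, 0), 8)
        assert fit.converged
        # oracle: dense grid search of the same least-squares objective
        best, best_cost = None, np.inf
        win = truth[8:25, 8:25]
        wy, wx = np.mgrid[8:25, 8:25]
        for cx in np.arange(0.0, 4.01, 0.05):
            for cy in np.arange(-1.0, 1.01, 0.05):
                g = np.exp(-(((wx - 16) - cx) ** 2 + ((wy - 16) - cy) ** 2) / 2.5**2)
                a = np.vstack([g.ravel(), np.ones(g.size)]).T
                coef, res, *_ = np.linalg.lstsq(a, win.ravel(), rcond=None)
                cost = float(res[0]) if len(res) else np.inf
                if cost < best_cost:
                    best, best_cost = (cx, cy), cost
        assert abs(fit.center[0] - best[0]) < 0.2
        assert abs(fit.center[1] - best[1]) < 0.2

    def test_nonfinite_slice_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_peak(np.full((9, 9), np.nan), (0, 0), 4)


class TestTrackPeaks:
    def test_translating_spot_centers_follow_the_motion(self):
        corr = correlation_function(translating_spot_stack(), max_lag=3)
        params = SticsParams(roi_size=32, min_lags_for_fit=3)
        centers, reasons = track_peaks(corr, params)
        assert [t for t, _ in centers] == [1, 2, 3]
        for tau, (xi, eta) in centers:
            assert abs(xi - tau) < 0.1 and abs(eta) < 0.1

    def test_static_structure_tracks_zero(self, rng):
        frame = rng.uniform(1, 5, size=(32, 32))
        stack = np.tile(frame, (5, 1, 1))
        corr = correlation_function(stack, max_lag=3)
        centers, _ = track_peaks(corr, SticsParams())
        assert len(centers) == 3
        for _, (xi, eta) in centers:
            assert abs(xi) < 0.05 and abs(eta) < 0.05

    def test_failed_lag_is_dropped_not_fatal(self):
        corr = correlation_function(translating_spot_stack(n_frames=5), max_lag=3)
        corrupted = CorrelationFunction(
            values=corr.values.copy(),
            roi_origin=corr.roi_origin,
            toi_start=corr.toi_start,
            normalization_used=corr.normalization_used,
        )
        corrupted.values[3] = 0.0  # τ=3 slice becomes constant → fit fails
        centers, reasons = track_peaks(corrupted, SticsParams())
        assert [t for t, _ in centers] == [1, 2]
        assert reasons == ["fit_failed"]


class TestVelocityFromPeaks:
    def test_one_pixel_per_frame_rightward(self):
        peaks = [(1, (1.0, 0.0)), (2, (2.0, 0.0)), (3, (3.0, 0.0))]
        vx, vy, r2 = velocity_from_peaks(peaks, pixel_size=0.14, frame_interval=15.0)
        assert np.isclose(vx, 0.56)  # 1 px/frame × 0.14 µm × 4 frames/min
        assert vy == 0.0 and r2 == 1.0

    def test_static_centers_give_zero_velocity(self):
        peaks = [(t, (0.0, 0.0)) for t in (1, 2, 3)]
        vx, vy, r2 = velocity_from_peaks(peaks, 0.14, 15.0)
        assert vx == 0.0 and vy == 0.0 and r2 == 1.0

    def test_diagonal_half_pixel_per_frame(self):
        peaks = [(t, (0.5 * t, 0.5 * t)) for t in (1, 2, 3)]
        vx, vy, r2 = velocity_from_peaks(peaks, 0.14, 15.0)
        assert np.isclose(vx, 0.28) and np.isclose(vy, -0.28)
        assert r2 == 1.0

    def test_upward_row_motion_is_positive_vy(self):
        peaks = [(t, (0.0, -1.0 * t)) for t in (1, 2, 3)]
        vx, vy, _ = velocity_from_peaks(peaks, 0.14, 15.0)
        assert vy > 0  # decreasing row lag = motion toward the image top

    def test_single_center_rejected(self):
        with pytest.raises(ValueError):
            velocity_from_peaks([(1, (1.0, 0.0))], 0.14, 15.0)


# ------------------------------------------------------------- analyze

def small_drift_series(seed=0, speed_px_per_frame=1.0):
    """Tiny drifting-spots video for fast end-to-end checks."""
    from sticsflow import preset, simulate
    speed_um_min = speed_px_per_frame * 0.14 * 60 / 15
    cfg = preset("contiguous", seed=seed, canvas=(40, 40), n_particles=30,
                 n_frames=8, drift_speed=speed_um_min)
    return simulate(cfg)[0]


SMALL_PARAMS = SticsParams(roi_size=16, roi_shift=8, toi_size=5, toi_shift=1,
                           min_lags_for_fit=3)

# pure-translation movies have no static fraction; skipping the immobile
# subtraction isolates the estimator from short-movie mean correlations
KINEMATIC_PARAMS = SticsParams(roi_size=16, roi_shift=8, toi_size=5,
                               toi_shift=1, min_lags_for_fit=3,
                               immobile="none")


class TestAnalyze:
    def test_every_roi_yields_exactly_one_vector(self):
        series = small_drift_series()
        fields = analyze(series, SMALL_PARAMS)
        n_rois = len(tile_rois(series.frame_shape, 16, 8))
        assert len(fields) == 8 - 5 + 1
        for f in fields:
            assert len(f.vectors) == n_rois

    def test_recovers_drift_velocity_and_direction(self):
        series = small_drift_series()
        fields = analyze(series, KINEMATIC_PARAMS)
        valid = [v for f in fields for v in f.valid_vectors]
        assert len(valid) > 20
        speeds = np.array([v.speed for v in valid])
        angles = np.array([v.angle for v in valid])
        assert abs(np.median(speeds) - 0.56) / 0.56 < 0.05
        assert np.median(np.abs(np.cos(np.deg2rad(angles)))) > 0.99

    def test_static_video_with_series_subtraction_is_all_empty(self):
        from sticsflow import preset, simulate
        cfg = preset("contiguous", seed=1, canvas=(40, 40), n_particles=30,
                     n_frames=6, drift_speed=0.0)
        series = simulate(cfg)[0]
        fields = analyze(series, SMALL_PARAMS)
        for f in fields:
            for v in f.vectors:
                assert not v.valid and v.rejection_reason == "empty_roi"

    def test_static_video_without_subtraction_yields_zero_vectors(self):
        from sticsflow import preset, simulate
        import dataclasses
        cfg = preset("contiguous", seed=1, canvas=(40, 40), n_particles=30,
                     n_frames=6, drift_speed=0.0)
        series = simulate(cfg)[0]
        params = dataclasses.replace(SMALL_PARAMS, immobile="none")
        valid = [v for f in analyze(series, params) for v in f.valid_vectors]
        assert len(valid) > 0
        assert all(v.speed < 0.02 for v in valid)

    def test_batched_path_matches_public_operations(self):
        """analyze() must equal the composition of the per-ROI primitives.

        Uses a sparse, well-separated-spot video so every peak fit is well
        conditioned: on such data the batched and per-ROI solvers converge
        to the same optimum (degenerate fits may differ in float ordering).
        """
        from sticsflow import preset, simulate
        cfg = preset("contiguous", seed=3, canvas=(40, 40), n_particles=10,
                     n_frames=8, drift_speed=1.0 * 0.14 * 60 / 15)
        series = simulate(cfg)[0]
        params = KINEMATIC_PARAMS
        fields = analyze(series, params)

        t0 = fields[1].toi_start
        toi = series.frames[t0 : t0 + params.toi_size]
        checked = 0
        for vec, (r0, c0) in zip(
            fields[1].vectors, tile_rois(series.frame_shape, 16, 8)
        ):
            stack = toi[:, r0 : r0 + 16, c0 : c0 + 16]
            corr = correlation_function(stack, params.max_lag,
                                        taper=params.taper)
            centers, _ = track_peaks(corr, params)
            if len(centers) < params.min_lags_for_fit:
                assert not vec.valid
                continue
            vx, vy, r2 = velocity_from_peaks(centers, series.pixel_size,
                                             series.frame_interval)
            np.testing.assert_allclose((vec.vx, vec.vy, vec.r2), (vx, vy, r2),
                                       rtol=1e-5, atol=1e-6)
            checked += 1
        assert checked >= 5

    def test_doubling_brightness_changes_no_vector(self):
        series = small_drift_series(seed=5)
        doubled = series.with_frames(2.0 * series.frames)
        a = analyze(series, KINEMATIC_PARAMS)
        b = analyze(doubled, KINEMATIC_PARAMS)
        for fa, fb in zip(a, b):
            for va, vb in zip(fa.vectors, fb.vectors):
                assert va.valid == vb.valid
                if va.valid:
                    np.testing.assert_allclose((va.vx, va.vy), (vb.vx, vb.vy),
                                               atol=1e-6)

    def test_short_series_rejected(self, random_series):
        with pytest.raises(ValueError):
            analyze(random_series, SticsParams(roi_size=16, toi_size=10))
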