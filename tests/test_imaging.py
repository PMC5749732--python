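import itertools

import numpy as np
import pytest

from circabiolum import (ImageStack, RoiSet, SpotTrack, Trace,
                         TrackingLostError, estimate_background, extract_trace,
                         kalman_stack_filter, remove_outliers, track_spot,
                         viability_qc)

from .conftest import make_cosine_trace


def brute_force_outlier_oracle(frame, radius, threshold):
    """Direct per-pixel median-replacement, edge-replicated."""
    h, w = frame.shape
    out = frame.copy().astype(float)
    padded = np.pad(frame.astype(float), radius, mode="edge")
    for r in range(h):
        for c in range(w):
            hood = padded[r:r + 2 * radius + 1, c:c + 2 * radius + 1]
            med = np.median(hood)
            if abs(frame[r, c] - med) > threshold:
                out[r, c] = med
    return out


class TestKalman:
    def test_constant_stack_is_fixed_point(self):
        stack = ImageStack(np.full((6, 4, 4), 17.0))
        out = kalman_stack_filter(stack)
        assert np.allclose(out.frames, 17.0)

    def test_zero_gain_passes_input_through(self):
        rng = np.random.default_rng(0)
        stack = ImageStack(rng.uniform(0, 255, (5, 8, 8)))
        out = kalman_stack_filter(stack, gain=0.0)
        assert np.allclose(out.frames, stack.frames)

    def test_single_pixel_hand_recursion(self):
        # defaults hold the posterior variance at V0, so K = 1 - gain = 0.2
        stack = ImageStack(np.array([10.0, 20.0, 20.0, 20.0]).reshape(4, 1, 1))
        out = kalman_stack_filter(stack).frames.ravel()
        assert np.allclose(out, [10.0, 12.0, 13.6, 14.88])

    def test_shape_and_dtype_preserved(self):
        stack = ImageStack(np.random.default_rng(1).integers(
            0, 255, (5, 6, 7)).astype(np.uint16))
        out = kalman_stack_filter(stack)
        assert out.frames.shape == stack.frames.shape
        assert out.frames.dtype == stack.frames.dtype

    def test_parameter_validation(self):
        stack = ImageStack(np.zeros((3, 2, 2)))
        with pytest.raises(ValueError):
            kalman_stack_filter(stack, gain=1.0)
        with pytest.raises(ValueError):
            kalman_stack_filter(stack, initial_variance=0.0)
        with pytest.raises(ValueError):
            ImageStack(np.zeros((1, 2, 2)))


class TestRemoveOutliers:
    def test_single_hot_pixel_replaced(self):
        frames = np.full((2, 9, 9), 50.0)
        frames[1, 4, 4] += 200.0
        out = remove_outliers(ImageStack(frames))
        assert out.frames[1, 4, 4] == pytest.approx(50.0)
        assert np.allclose(out.frames[0], 50.0)

    def test_deviation_equal_to_threshold_kept(self):
        frames = np.full((2, 9, 9), 50.0)
        frames[1, 4, 4] += 100.0  # exactly the threshold: strict inequality
        out = remove_outliers(ImageStack(frames), threshold=100.0)
        assert out.frames[1, 4, 4] == pytest.approx(150.0)

    def test_matches_brute_force_oracle_on_random_frame(self):
        rng = np.random.default_rng(8)
        frame = rng.uniform(0, 255, (12, 14))
        out = remove_outliers(ImageStack(np.stack([frame, frame])),
                              radius_px=1, threshold=100.0)
        oracle = brute_force_outlier_oracle(frame, 1, 100.0)
        assert np.allclose(out.frames[0], oracle)

    def test_idempotent_on_sparse_outliers(self):
        rng = np.random.default_rng(9)
        frame = 40.0 + rng.normal(0, 3.0, (16, 16))
        for r, c in [(2, 3), (8, 11), (14, 5)]:
            frame[r, c] += 400.0
        stack = ImageStack(np.stack([frame, frame]))
        once = remove_outliers(stack)
        twice = remove_outliers(once)
        assert np.allclose(once.frames, twice.frames)


class TestBackground:
    def test_constant_frames(self):
        stack = ImageStack(np.full((4, 10, 10), 7.0))
        rois = RoiSet([(0, 0, 2, 2), (0, 8, 2, 10), (8, 0, 10, 2), (8, 8, 10, 10)])
        assert np.allclose(estimate_background(stack, rois), 7.0)

    def test_mean_of_roi_means(self):
        frame = np.zeros((4, 8))
        frame[0:2, 0:2] = 2.0
        frame[0:2, 2:4] = 4.0
        frame[0:2, 4:6] = 6.0
        frame[0:2, 6:8] = 8.0
        stack = ImageStack(np.stack([frame, frame]))
        rois = RoiSet([(0, 0, 2, 2), (0, 2, 2, 4), (0, 4, 2, 6), (0, 6, 2, 8)])
        assert np.allclose(estimate_background(stack, rois), 5.0)

    def test_recovers_known_background_level(self):
        from circabiolum import OscillatorParams, render_movie, simulate_population
        p = OscillatorParams(tau_sd=0, noise_phase_sd=0, noise_obs_sd=0, seed=1,
                             forcing_eps=0.0)
        cells = simulate_population(1, p, None, duration_h=24.0)
        stack, _ = render_movie(cells, frame_shape_px=(40, 40),
                                background_level=12.0, noise_sd=1.0, seed=2)
        # cell-free regions well away from the rendered spot
        rois = RoiSet([(0, 30, 5, 40), (30, 0, 40, 5), (20, 32, 25, 40),
                       (35, 30, 40, 40)])
        bg = estimate_background(stack, rois)
        assert np.allclose(bg, 12.0, atol=3 * 1.0 / np.sqrt(100))


class TestTracking:
    def _spot_stack(self, path, shape=(24, 24), value=100.0):
        frames = np.zeros((len(path),) + shape)
        for f, (r, c) in enumerate(path):
            frames[f, r, c] = value
        return ImageStack(frames)

    def test_static_spot_constant_path(self):
        stack = self._spot_stack([(10, 12)] * 6)
        track = track_spot(stack, (10, 12), max_step_px=3, subpixel=False)
        assert np.all(track.positions == [10, 12])

    def test_follows_moving_spot(self):
        path = [(5, 5), (5, 6), (6, 7), (7, 7), (8, 8), (8, 9)]
        stack = self._spot_stack(path)
        track = track_spot(stack, (5, 5), max_step_px=3, motion_penalty=0.1,
                           subpixel=False)
        assert np.array_equal(track.positions, np.array(path, dtype=float))

    def test_high_motion_penalty_prefers_smooth_path(self):
        # bright decoy jumps far away; smooth dim spot stays near home
        frames = np.zeros((5, 20, 20))
        smooth = [(10, 5), (10, 6), (10, 7), (10, 8), (10, 9)]
        decoy = [(10, 5), (14, 9), (15, 10), (14, 9), (15, 10)]
        for f in range(5):
            frames[f][smooth[f]] = 80.0
            if f > 0:
                frames[f][decoy[f]] = 100.0
        stack = ImageStack(frames)
        track = track_spot(stack, (10, 5), max_step_px=6, motion_penalty=0.3,
                           subpixel=False)
        assert np.array_equal(track.positions, np.array(smooth, dtype=float))

    def test_dp_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        frames = rng.uniform(0, 60, (5, 10, 10))
        frames[:, 4:7, 4:7] += 60.0
        stack = ImageStack(frames)
        max_step, mp = 3.0, 0.3
        track = track_spot(stack, (5, 5), max_step_px=max_step,
                           motion_penalty=mp, subpixel=False)

        # oracle: enumerate every admissible candidate sequence
        from scipy import ndimage
        peak = frames.max()
        cand = []
        prev = [np.array([5.0, 5.0])]
        for f in range(5):
            mx = ndimage.maximum_filter(frames[f], size=3, mode="nearest")
            pts = np.argwhere(frames[f] >= mx)
            pts = [p for p in pts
                   if min(np.hypot(*(p - q)) for q in prev) <= max_step]
            cand.append(pts)
            prev = pts
        best_score, best_path = -np.inf, None
        for combo in itertools.product(*cand):
            ok = all(np.hypot(*(np.asarray(b) - np.asarray(a))) <= max_step
                     for a, b in zip(combo, combo[1:]))
            if not ok:
                continue
            score = sum(frames[f][tuple(p)] / peak
                        for f, p in enumerate(combo))
            score -= mp * sum(((np.asarray(b) - np.asarray(a)) ** 2).sum()
                              for a, b in zip(combo, combo[1:]))
            if score > best_score:
                best_score, best_path = score, combo
        assert np.array_equal(track.positions,
                              np.array(best_path, dtype=float))

    def test_tracking_lost_names_frame(self):
        # a strictly increasing ramp has no local maximum except the far
        # corner, so the reachable region around the old spot goes empty
        frames = np.zeros((4, 12, 12))
        frames[:2, 5, 5] = 50.0
        ramp = np.add.outer(np.arange(12.0), np.arange(12.0))
        frames[2] = ramp
        frames[3] = ramp
        stack = ImageStack(frames)
        with pytest.raises(TrackingLostError) as exc:
            track_spot(stack, (5, 5), max_step_px=2.0, subpixel=False)
        assert exc.value.frame in (2, 3)


class TestExtractAndQC:
    def test_constant_frames_constant_trace(self):
        stack = ImageStack(np.full((5, 8, 8), 33.0))
        track = SpotTrack.fixed("c", (4, 4), 5)
        tr = extract_trace(stack, track)
        assert np.allclose(tr.values, 33.0)
        assert np.allclose(tr.time_h, np.arange(5) * 0.5)

    def test_single_pixel_spot_divided_by_window(self):
        frames = np.zeros((3, 9, 9))
        frames[:, 4, 4] = 90.0
        tr = extract_trace(ImageStack(frames), SpotTrack.fixed("c", (4, 4), 3))
        assert np.allclose(tr.values, 10.0)  # 90 / 9 pixels

    def test_border_window_clipped(self):
        frames = np.full((2, 6, 6), 12.0)
        tr = extract_trace(ImageStack(frames), SpotTrack.fixed("c", (0, 0), 2))
        assert np.allclose(tr.values, 12.0)

    def test_qc_keeps_stable_sinusoid(self):
        tr = make_cosine_trace(a=30, offset=100, duration_h=120)
        assert viability_qc(tr).keep

    def test_qc_excludes_strong_reduction(self):
        t = np.arange(0, 120.0001, 0.5)
        v = (100 + 30 * np.cos(2 * np.pi * t / 24)) * np.exp(-t / 15.0) + 0.01
        res = viability_qc(Trace("dying", t, v))
        assert not res.keep
        assert res.reason == "strong reduction"

    def test_qc_excludes_flat_trace(self):
        t = np.arange(0, 120.0001, 0.5)
        res = viability_qc(Trace("flat", t, np.full_like(t, 180.0)))
        assert not res.keep
        assert res.reason == "loss of rhythmicity"


class TestPipelineEquivariance:
    def test_constant_offset_propagates_to_traces(self):
        rng = np.random.default_rng(2)
        frames = rng.uniform(10, 60, (6, 12, 12))
        stack = ImageStack(frames)
        shifted = ImageStack(frames + 25.0)
        for fn in (lambda s: kalman_stack_filter(s),
                   lambda s: remove_outliers(s, threshold=30.0)):
            a = fn(stack).frames
            b = fn(shifted).frames
            assert np.allclose(b, a + 25.0)
        track = SpotTrack.fixed("c", (6, 6), 6)
        ta = extract_trace(stack, track)
        tb = extract_trace(shifted, track)
        assert np.allclose(tb.values, ta.values + 25.0)
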