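"""From bioluminescence image stacks to per-cell intensity traces.

Temporal Kalman denoising, spatial outlier removal, background estimation
from cell-free ROIs, dynamic-programming spot tracking, windowed intensity
extraction and viability QC.  Pixel coordinates are 0-based (row, col) with
the origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import TrackingLostError
from .traces import Trace

__all__ = [
    "ImageStack",
    "SpotTrack",
    "RoiSet",
    "kalman_stack_filter",
    "remove_outliers",
    "estimate_background",
    "track_spot",
    "extract_trace",
    "viability_qc",
    "QCResult",
]


@dataclass
class ImageStack:
    """time x height x width gray-value array with a frame interval in hours."""

    frames: np.ndarray
    dt_h: float = 0.5

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("stack must be 3-D with at least 2 frames")
        if self.dt_h <= 0:
            raise ValueError("dt_h must be positive")
        if np.any(self.frames < 0):
            raise ValueError("gray values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def write_tiff(self, path) -> None:
        import tifffile
        arr = np.clip(np.round(self.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(path, arr)

    @classmethod
    def read_tiff(cls, path, dt_h: float = 0.5) -> "ImageStack":
        import tifffile
        return cls(frames=tifffile.imread(path).astype(float), dt_h=dt_h)


@dataclass
class SpotTrack:
    cell_id: str
    positions: np.ndarray  # (n_frames, 2) row/col
    window_radius_px: int = 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n_frames, 2)")

    @classmethod
    def fixed(cls, cell_id: str, position, n_frames: int,
              window_radius_px: int = 1) -> "SpotTrack":
        """Immobile-cell track (manual-ROI style): one position, all frames."""
        pos = np.tile(np.asarray(position, dtype=float), (n_frames, 1))
        return cls(cell_id, pos, window_radius_px)


@dataclass
class RoiSet:
    """Rectangles (row0, col0, row1, col1), half-open."""

    rectangles: list[tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        if not self.rectangles:
            raise ValueError("RoiSet must contain at least one rectangle")
        for r0, c0, r1, c1 in self.rectangles:
            if r1 <= r0 or c1 <= c0:
                raise ValueError("ROI rectangles must have positive area")


# -- temporal denoising -----------------------------------------------------

def kalman_stack_filter(stack: ImageStack, gain: float = 0.8,
                        initial_variance: float = 0.05) -> ImageStack:
    """Per-pixel scalar Kalman smoother along the time axis.

    Recursion (per pixel): x0 = z0, P0 = initial_variance; for t >= 1
    ``K = P/(P + R)``, ``x_t = x_{t-1} + K (z_t - x_{t-1})``,
    ``P <- (1 - K) P + q`` with the gain-derived measurement variance
    ``R = gain * V0 / (1 - gain)`` and process noise ``q = (1 - gain) * V0``.
    This choice holds P at V0, so the Kalman gain is constant at
    ``1 - gain``: the filter is the steady-state exponential smoother the
    ImageJ plugin implements, with ``gain`` the weight of the running
    estimate (plugin defaults 0.8 and 0.05).  ``gain = 0`` trusts the
    measurement fully and returns the input unchanged.
    """
    if not 0.0 <= gain < 1.0:
        raise ValueError("gain must lie in [0, 1)")
    if initial_variance <= 0:
        raise ValueError("initial_variance must be positive")
    z = stack.frames.astype(float)
    out = np.empty_like(z)
    out[0] = z[0]
    R = gain * initial_variance / (1.0 - gain)
    q = (1.0 - gain) * initial_variance
    P = initial_variance
    est = z[0].copy()
    for t in range(1, z.shape[0]):
        K = P / (P + R) if (P + R) > 0 else 1.0
        est = est + K * (z[t] - est)
        P = (1.0 - K) * P + q
        out[t] = est
    if np.issubdtype(stack.frames.dtype, np.integer):
        out = np.round(out).astype(stack.frames.dtype)
    return ImageStack(frames=out, dt_h=stack.dt_h)


# -- spatial outlier removal ------------------------------------------------

def remove_outliers(stack: ImageStack, radius_px: int = 1,
                    threshold: float = 100.0) -> ImageStack:
    """Replace pixels deviating from their neighbourhood median.

    Per frame, a pixel whose value differs from the median of its
    (2r+1) x (2r+1) neighbourhood (edges replicated) by *strictly more*
    than ``threshold`` is replaced by that median; bright and dark outliers
    are both handled.  Defaults radius 1, threshold 100.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    size = 2 * radius_px + 1
    out = stack.frames.copy()
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        med = ndimage.median_filter(frame, size=size, mode="nearest")
        mask = np.abs(frame.astype(float) - med.astype(float)) > threshold
        out[t] = np.where(mask, med, frame)
    return ImageStack(frames=out, dt_h=stack.dt_h)


# -- background -------------------------------------------------------------

def estimate_background(stack: ImageStack, background_rois: RoiSet) -> np.ndarray:
    """Per-frame background: mean of the (typically four) cell-free ROI means."""
    series = np.empty(stack.n_frames)
    for t in range(stack.n_frames):
        means = []
        for r0, c0, r1, c1 in background_rois.rectangles:
            patch = stack.frames[t, r0:r1, c0:c1]
            if patch.size == 0:
                raise ValueError("empty background ROI")
            means.append(float(patch.mean()))
        series[t] = float(np.mean(means))
    return series


# -- tracking ---------------------------------------------------------------

def _local_maxima(frame: np.ndarray, region_mask: np.ndarray) -> np.ndarray:
    mx = ndimage.maximum_filter(frame, size=3, mode="nearest")
    cand = (frame >= mx) & region_mask
    return np.argwhere(cand)


def track_spot(stack: ImageStack, start_pos, max_step_px: float = 5.0,
               motion_penalty: float = 1.0, cell_id: str = "",
               window_radius_px: int = 1, subpixel: bool = True) -> SpotTrack:
    """Globally optimal spot path by dynamic programming.

    Candidate positions in each frame are 3x3 local intensity maxima within
    ``max_step_px`` (Euclidean) of any candidate of the previous frame; the
    path score is the sum of normalised intensities (relative to the stack
    maximum) minus ``motion_penalty`` times the summed squared displacements
    in pixels, maximised globally (Viterbi-style, not greedy) so the track
    can ride out the dim trough of a bioluminescence cycle.  The integer
    path is optionally refined to sub-pixel precision by a local
    centre-of-mass step.  A frame with no reachable candidate raises
    :class:`TrackingLostError` naming the frame.
    """
    frames = stack.frames.astype(float)
    n, h, w = frames.shape
    start = np.asarray(start_pos, dtype=float)
    if not (0 <= start[0] < h and 0 <= start[1] < w):
        raise ValueError("start_pos outside frame 0")

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    stack_peak = frames.max()

    def norm_int(f, pts):
        vals = frames[f][pts[:, 0], pts[:, 1]]
        return vals / stack_peak if stack_peak > 0 else np.zeros(len(pts))

    region0 = (rows - start[0]) ** 2 + (cols - start[1]) ** 2 <= max_step_px ** 2
    pts = _local_maxima(frames[0], region0)
    if len(pts) == 0:
        pts = np.array([np.round(start).astype(int)])
    scores = norm_int(0, pts)
    back: list[np.ndarray] = []
    all_pts = [pts]
    for f in range(1, n):
        occ = np.ones((h, w), dtype=bool)
        occ[pts[:, 0], pts[:, 1]] = False
        region = ndimage.distance_transform_edt(occ) <= max_step_px
        new_pts = _local_maxima(frames[f], region)
        if len(new_pts) == 0:
            raise TrackingLostError(f)
        d2 = ((new_pts[:, None, 0] - pts[None, :, 0]) ** 2
              + (new_pts[:, None, 1] - pts[None, :, 1]) ** 2).astype(float)
        reach = d2 <= max_step_px ** 2
        trans = np.where(reach, scores[None, :] - motion_penalty * d2, -np.inf)
        best_prev = np.argmax(trans, axis=1)
        best_val = trans[np.arange(len(new_pts)), best_prev]
        keep = np.isfinite(best_val)
        if not np.any(keep):
            raise TrackingLostError(f)
        new_pts, best_prev, best_val = new_pts[keep], best_prev[keep], best_val[keep]
        scores = best_val + norm_int(f, new_pts)
        back.append(best_prev)
        all_pts.append(new_pts)
        pts = new_pts

    path = np.empty((n, 2))
    j = int(np.argmax(scores))
    for f in range(n - 1, -1, -1):
        path[f] = all_pts[f][j]
        if f > 0:
            j = int(back[f - 1][j])
    if subpixel:
        path = _refine_subpixel(frames, path)
    return SpotTrack(cell_id=cell_id or "spot", positions=path,
                     window_radius_px=window_radius_px)


def _refine_subpixel(frames, path, radius: int = 2):
    """Centre-of-mass refinement (background-subtracted, shift capped at 1 px)."""
    n, h, w = frames.shape
    out = path.copy()
    for f in range(n):
        cr, cc = int(round(path[f, 0])), int(round(path[f, 1]))
        r0, r1 = max(0, cr - radius), min(h, cr + radius + 1)
        c0, c1 = max(0, cc - radius), min(w, cc + radius + 1)
        patch = frames[f, r0:r1, c0:c1] - frames[f, r0:r1, c0:c1].min()
        tot = patch.sum()
        if tot <= 0:
            continue
        rr = np.arange(r0, r1)[:, None]
        cc2 = np.arange(c0, c1)[None, :]
        com_r = float((patch * rr).sum() / tot)
        com_c = float((patch * cc2).sum() / tot)
        out[f, 0] = cr + np.clip(com_r - cr, -1.0, 1.0)
        out[f, 1] = cc + np.clip(com_c - cc, -1.0, 1.0)
    return out


# -- extraction & QC --------------------------------------------------------

def extract_trace(stack: ImageStack, track: SpotTrack,
                  window_radius_px: int | None = None) -> Trace:
    """Mean gray value in a (2r+1)^2 window around the tracked position.

    The default window is 3x3 (r = 1).  Windows are clipped at the frame
    borders; the mean is then over the in-frame pixels only.
    """
    r = track.window_radius_px if window_radius_px is None else window_radius_px
    h, w = stack.shape
    vals = np.empty(stack.n_frames)
    for f in range(stack.n_frames):
        cr, cc = np.round(track.positions[f]).astype(int)
        r0, r1 = max(0, cr - r), min(h, cr + r + 1)
        c0, c1 = max(0, cc - r), min(w, cc + r + 1)
        vals[f] = float(stack.frames[f, r0:r1, c0:c1].mean())
    time_h = np.arange(stack.n_frames) * stack.dt_h
    return Trace(cell_id=track.cell_id, time_h=time_h, values=vals)


@dataclass
class QCResult:
    cell_id: str
    keep: bool
    reason: str | None = None


def viability_qc(trace: Trace, min_final_fraction: float = 0.1,
                 rhythm_window_h: float = 48.0) -> QCResult:
    """Exclude dying or arrhythmic cells.

    A cell is excluded when the mean of its final 24 h falls below
    ``min_final_fraction`` of the mean of its first 24 h ("strong
    reduction"), or when the peak picker finds no peak in the final
    ``rhythm_window_h`` ("loss of rhythmicity").
    """
    from .phase import pick_peaks

    if trace.duration_h < 48.0:
        raise ValueError("viability QC needs at least 2 days of data")
    t, v = trace.time_h, trace.values
    first = v[t <= t[0] + 24.0]
    last = v[t >= t[-1] - 24.0]
    if first.mean() > 0 and last.mean() < min_final_fraction * first.mean():
        return QCResult(trace.cell_id, keep=False, reason="strong reduction")
    tail = trace.restrict(t[-1] - rhythm_window_h, t[-1] + trace.dt_h)
    if len(pick_peaks(tail)) == 0:
        return QCResult(trace.cell_id, keep=False, reason="loss of rhythmicity")
    return QCResult(trace.cell_id, keep=True)
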