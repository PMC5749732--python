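"""Per-cell bioluminescence traces and their preprocessing.

The observable is PER2::LUC bioluminescence in camera gray values sampled on
a uniform grid (0.5 h by default, the 30-min exposure).  Preprocessing
follows the standard single-cell pipeline: normalisation of the maximum to
gray level 255, subtraction of a per-frame background estimate, and trend
elimination by subtracting a 24-h running average (with the raw minimum added
back so magnitudes stay comparable).  Each step sets a provenance flag on the
trace; flags are never unset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SegmentationError
from .protocol import TemperatureProtocol

__all__ = [
    "Trace",
    "normalize_max",
    "subtract_background",
    "detrend_running_average",
    "segment",
    "traces_to_frame",
    "frame_to_traces",
]


@dataclass
class Trace:
    """One cell's time series on a uniform grid.

    ``time_h`` is in hours from the start of the recording; ``values`` are
    gray levels (floats after processing).  ``stage`` optionally labels each
    sample 'before'/'during'/'after'.
    """

    cell_id: str
    time_h: np.ndarray
    values: np.ndarray
    stage: np.ndarray | None = None
    normalized: bool = False
    background_subtracted: bool = False
    detrended: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_h.shape != self.values.shape:
            raise ValueError("time and values must have the same length")
        if len(self.time_h) >= 2:
            steps = np.diff(self.time_h)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def dt_h(self) -> float:
        return float(self.time_h[1] - self.time_h[0])

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])

    def with_values(self, values, **flag_updates) -> "Trace":
        """Copy with new values; provenance flags may only be switched on."""
        for name, val in flag_updates.items():
            if getattr(self, name) and not val:
                raise ValueError(f"provenance flag {name!r} cannot be unset")
        return replace(self, values=np.asarray(values, dtype=float), **flag_updates)

    def restrict(self, lo_h: float, hi_h: float) -> "Trace":
        """Sub-trace with lo_h <= t < hi_h (half-open)."""
        m = (self.time_h >= lo_h) & (self.time_h < hi_h)
        return replace(self, time_h=self.time_h[m], values=self.values[m],
                       stage=None if self.stage is None else np.asarray(self.stage)[m])


def normalize_max(trace: Trace, target: float = 255.0) -> Trace:
    """Scale so the maximum gray value equals ``target`` (255 by default)."""
    peak = float(np.max(trace.values))
    if peak <= 0:
        raise ValueError("cannot normalize a trace with non-positive maximum")
    return trace.with_values(trace.values * (target / peak), normalized=True)


def subtract_background(trace: Trace, background_series) -> Trace:
    """Subtract a per-sample background estimate (negatives are allowed)."""
    bg = np.asarray(background_series, dtype=float)
    if bg.shape != trace.values.shape:
        raise ValueError("background series length must match the trace")
    return trace.with_values(trace.values - bg, background_subtracted=True)


def _running_mean(values: np.ndarray, window: int) -> np.ndarray:
    # centred moving average, truncated (shrinking) at the edges
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def detrend_running_average(trace: Trace, window_h: float = 24.0) -> Trace:
    """Remove slow trends by subtracting a centred 24-h running average.

    The raw trace's minimum gray level is added back afterwards so detrended
    traces remain on a comparable magnitude scale.  The first and last half
    window are computed with a truncated window and flagged as edge-affected
    in ``meta['edge_affected_h']``.
    """
    window = int(round(window_h / trace.dt_h)) + 1  # 49 samples for 24 h at 0.5 h
    if len(trace.values) < window:
        raise ValueError("trace shorter than the detrending window")
    trend = _running_mean(trace.values, window)
    out = trace.values - trend + float(np.min(trace.values))
    new = trace.with_values(out, detrended=True)
    new.meta = dict(trace.meta, edge_affected_h=window_h / 2)
    return new


def segment(trace: Trace, protocol: TemperatureProtocol,
            last_cycles: int = 3) -> dict[str, Trace]:
    """Partition a trace into Before/During/After (half-open at the cuts).

    Also returns ``during_last`` — the During sub-window restricted to the
    last ``last_cycles`` temperature cycles, the window used for During-period
    fits to minimise transients.  An empty Before (protocol starting at 0) is
    allowed and flagged in the returned trace's ``meta``.
    """
    t0, t1 = float(trace.time_h[0]), float(trace.time_h[-1])
    if protocol.start_h < t0 - 1e-9 or protocol.end_h > t1 + trace.dt_h + 1e-9:
        raise SegmentationError(
            f"protocol [{protocol.start_h}, {protocol.end_h}) h is outside the "
            f"recording [{t0}, {t1}] h")
    parts = {
        "before": trace.restrict(t0, protocol.start_h),
        "during": trace.restrict(protocol.start_h, protocol.end_h),
        "after": trace.restrict(protocol.end_h, t1 + trace.dt_h),
    }
    lo, hi = protocol.last_cycles_window(last_cycles)
    parts["during_last"] = trace.restrict(lo, hi)
    for name in ("before", "during", "after"):
        if len(parts[name].time_h) == 0:
            parts[name].meta = dict(parts[name].meta, empty_stage=name)
    return parts


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Tidy CSV layout: columns cell_id, time_h, value, stage."""
    rows = []
    for tr in traces:
        stage = tr.stage if tr.stage is not None else [""] * len(tr.time_h)
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id,
            "time_h": tr.time_h,
            "value": tr.values,
            "stage": stage,
        }))
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[Trace]:
    out = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("time_h")
        stage = g["stage"].to_numpy() if "stage" in g else None
        out.append(Trace(str(cell_id), g["time_h"].to_numpy(),
                         g["value"].to_numpy(), stage=stage))
    return out
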