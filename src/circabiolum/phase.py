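"""Peak picking, circadian time, phase shifts, PRC/ARC assembly.

Circadian time conventions follow the temperature-cycle literature: during
entrainment CT12 is the end of the cold phase (middle of the circadian day);
in free run the PER2::LUC bioluminescence peak defines CT18, and real hours
elapsed since a reference peak are converted to circadian hours by
multiplying with 24/tau (division convention; the multiplicative variant is
available behind ``ct_mode`` for comparison).  Phase shifts are signed so
that a peak arriving *later* than expected is a delay and negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .cosinor import CosinorResults, circadian_filter
from .protocol import TemperatureProtocol
from .traces import Trace, _running_mean

__all__ = [
    "PeakSet",
    "PhaseShift",
    "pick_peaks",
    "to_circadian_free_run",
    "to_circadian_entrained",
    "expected_peak",
    "phase_shift",
    "onset_ct",
    "entrainment_filter",
    "build_prc",
    "amplitude_response",
    "phase_relationship_table",
]

#: minimum separation between detected peaks (half a circadian cycle)
MIN_PEAK_SEPARATION_H = 12.0


@dataclass
class PeakSet:
    cell_id: str
    peak_times_h: np.ndarray
    peak_heights: np.ndarray
    stages: list[str] = field(default_factory=list)
    rejected: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peak_times_h = np.asarray(self.peak_times_h, dtype=float)
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)
        if len(self.peak_times_h) > 1:
            gaps = np.diff(self.peak_times_h)
            if np.any(gaps <= 0):
                raise ValueError("peak times must be strictly increasing")
            if np.any(gaps < MIN_PEAK_SEPARATION_H - 1e-9):
                raise ValueError("peaks closer than half a circadian cycle")

    def __len__(self) -> int:
        return len(self.peak_times_h)

    def in_window(self, lo_h: float, hi_h: float) -> np.ndarray:
        m = (self.peak_times_h >= lo_h) & (self.peak_times_h < hi_h)
        return self.peak_times_h[m]


@dataclass
class PhaseShift:
    """Response to a single cold stimulus, in circadian hours.

    ``shift_ct`` < 0 is a delay (the actual peak came later than the peak
    extrapolated from Before), > 0 an advance.
    """

    cell_id: str
    expected_peak_h: float
    actual_peak_h: float
    tau_before_h: float
    shift_ct: float
    onset_ct: float = np.nan


def _ct_scale(tau_h: float, ct_mode: str) -> float:
    """Circadian hours per real hour for a cell of period ``tau_h``."""
    if ct_mode == "division":
        return 24.0 / tau_h
    if ct_mode == "multiplication":
        return tau_h / 24.0
    raise ValueError("ct_mode must be 'division' or 'multiplication'")


def pick_peaks(trace_segment, smooth_window_h: float = 11.0, fit_points: int = 30,
               min_separation_h: float = MIN_PEAK_SEPARATION_H) -> PeakSet:
    """Detect bioluminescence peaks by smoothing + local parabola fits.

    Candidates are local maxima of an 11-h centred running average separated
    by at least half a circadian cycle; around each candidate an ordinary
    least-squares parabola is fitted to the *unsmoothed* processed data over
    ``fit_points`` samples (15 h at 0.5-h sampling) and the vertex taken as
    the peak time.  Candidates whose parabola is not concave-down or whose
    vertex escapes the fit window are rejected with a recorded reason.
    Returns an empty set (never raises) when nothing qualifies.
    """
    if isinstance(trace_segment, Trace):
        t, v, cell = trace_segment.time_h, trace_segment.values, trace_segment.cell_id
    else:
        t, v = np.asarray(trace_segment[0], float), np.asarray(trace_segment[1], float)
        cell = ""
    if len(t) < 4:
        return PeakSet(cell, [], [])
    dt = t[1] - t[0]
    win = int(round(smooth_window_h / dt)) + 1
    if len(v) < win:
        return PeakSet(cell, [], [])
    smooth = _running_mean(v, win)
    distance = max(1, int(round(min_separation_h / dt)))
    idx, _ = signal.find_peaks(smooth, distance=distance)

    times, heights, rejected = [], [], []
    half = fit_points // 2
    for i in idx:
        i0 = max(0, min(i - half, len(v) - fit_points))
        i1 = i0 + fit_points
        if i1 > len(v):
            rejected.append({"candidate_h": t[i], "reason": "window outside segment"})
            continue
        tw, vw = t[i0:i1], v[i0:i1]
        # centre the regressor for conditioning
        x = tw - tw.mean()
        c2, c1, c0 = np.polyfit(x, vw, 2)
        if c2 >= 0:
            rejected.append({"candidate_h": t[i], "reason": "not concave-down"})
            continue
        vertex = tw.mean() - c1 / (2.0 * c2)
        if not (tw[0] - 1e-9 <= vertex <= tw[-1] + 1e-9):
            rejected.append({"candidate_h": t[i], "reason": "vertex outside fit window"})
            continue
        times.append(vertex)
        heights.append(c0 - c1 ** 2 / (4.0 * c2))
    order = np.argsort(times)
    times = list(np.asarray(times)[order])
    heights = list(np.asarray(heights)[order])
    # enforce the separation invariant on the fitted vertices (keep the higher)
    keep_t, keep_h = [], []
    for pt, ph in zip(times, heights):
        if keep_t and pt - keep_t[-1] < min_separation_h:
            if ph > keep_h[-1]:
                keep_t[-1], keep_h[-1] = pt, ph
            continue
        keep_t.append(pt)
        keep_h.append(ph)
    return PeakSet(cell, keep_t, keep_h, rejected=rejected)


def to_circadian_free_run(peak_time_h: float, tau_before: float,
                          reference_peak_h: float,
                          ct_mode: str = "division") -> float:
    """Circadian time of a peak in free run, anchored at CT18 = PER2 peak.

    Real hours elapsed since the reference bioluminescence peak are rescaled
    by the cell's own period and added to CT18, modulo 24.
    """
    if not 18.0 <= tau_before <= 30.0:
        raise ValueError("tau_before outside the circadian band")
    if reference_peak_h is None or not np.isfinite(reference_peak_h):
        raise ValueError("a reference peak is required to anchor CT18")
    return float((18.0 + (peak_time_h - reference_peak_h) * _ct_scale(tau_before, ct_mode))
                 % 24.0)


def to_circadian_entrained(peak_time_h: float, protocol: TemperatureProtocol) -> float:
    """Circadian time of a peak during cycles: CT12 = end of the cold phase.

    One circadian day (24 CT hours) is rescaled to the zeitgeber period T,
    so CT = 12 + (t - cold_end) * 24/T, using the nearest preceding cold end
    (the cold ends are T-periodic, so a single modulo suffices).
    """
    if not (protocol.start_h <= peak_time_h < protocol.end_h):
        raise ValueError("peak is outside the During window")
    first_cold_end = protocol.start_h + protocol.cold_h
    return float((12.0 + (peak_time_h - first_cold_end) * 24.0 / protocol.cycle_length_h)
                 % 24.0)


def expected_peak(before_fit: CosinorResults, window_start_h: float) -> float:
    """Extrapolate the Before cosine fit to its first peak at/after a time."""
    if not circadian_filter(before_fit):
        raise ValueError("Before fit rejected; cannot extrapolate an expected peak")
    return before_fit.peak_time_after(window_start_h)


def phase_shift(expected_peak_h: float, actual_peak_h: float, tau_before: float,
                ct_mode: str = "division") -> float:
    """Signed phase shift in circadian hours: (expected - actual) * 24/tau.

    A later-than-expected peak gives a negative value (delay), an earlier
    peak a positive one (advance).
    """
    if abs(expected_peak_h - actual_peak_h) >= tau_before / 2.0:
        raise ValueError(
            "expected and actual peak are more than half a cycle apart; "
            "ambiguous cycle pairing")
    return float((expected_peak_h - actual_peak_h) * _ct_scale(tau_before, ct_mode))


def match_actual_peak(expected_peak_h: float, peaks: PeakSet,
                      tau_before: float) -> float:
    """The picked peak nearest the expected one, required within +/- tau/2."""
    if len(peaks) == 0:
        raise ValueError("no picked peaks to match against")
    d = np.abs(peaks.peak_times_h - expected_peak_h)
    j = int(np.argmin(d))
    if d[j] >= tau_before / 2.0:
        raise ValueError("no picked peak within half a cycle of the expected peak")
    return float(peaks.peak_times_h[j])


def onset_ct(stimulus_onset_h: float, before_peaks: PeakSet | np.ndarray,
             tau_before: float, ct_mode: str = "division") -> float:
    """Circadian time of a stimulus onset, anchored at CT18 = last Before peak."""
    pt = before_peaks.peak_times_h if isinstance(before_peaks, PeakSet) \
        else np.asarray(before_peaks, dtype=float)
    prior = pt[pt <= stimulus_onset_h + 1e-9]
    if len(prior) == 0:
        raise ValueError("no Before peak precedes the stimulus onset")
    ref = float(prior[-1])
    return float((18.0 + (stimulus_onset_h - ref) * _ct_scale(tau_before, ct_mode)) % 24.0)


def entrainment_filter(during_fit: CosinorResults, protocol: TemperatureProtocol,
                       tol_h: float = 1.0) -> bool:
    """Accept cells whose During period is within +/- tol_h of the T-cycle."""
    if not circadian_filter(during_fit):
        return False
    return abs(during_fit.period_h - protocol.cycle_length_h) <= tol_h


def build_prc(shifts: list[PhaseShift], amp_folds: list[float] | None = None,
              delay_range_ct: tuple[float, float] = (6.0, 18.0),
              poly_order: int = 4) -> dict:
    """Assemble a phase-response table with group statistics.

    Shifts whose stimulus onset fell in ``[CT6, CT18)`` form the delay group,
    the remainder the advance group (the convention of the fibroblast cold-
    pulse response curve).  Group means +/- SEM and a two-sample t-test of
    the group means are returned; a 4th-order polynomial fitted on onset CT
    unwrapped at the delay-range start provides the display curve only.
    """
    if len(shifts) < 3:
        raise ValueError("need at least 3 shifts to assemble a PRC")
    df = pd.DataFrame({
        "cell_id": [s.cell_id for s in shifts],
        "onset_ct": [s.onset_ct for s in shifts],
        "shift_ct": [s.shift_ct for s in shifts],
    })
    if amp_folds is not None:
        df["amp_fold"] = amp_folds
    lo, hi = delay_range_ct
    in_delay = (df["onset_ct"] >= lo) & (df["onset_ct"] < hi)
    df["group"] = np.where(in_delay, "delay", "advance")

    def _group_stats(vals):
        vals = np.asarray(vals, dtype=float)
        if len(vals) == 0:
            return {"n": 0, "mean": np.nan, "sem": np.nan, "defined": False}
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        return {"n": len(vals), "mean": float(vals.mean()), "sem": sem, "defined": True}

    d_vals = df.loc[df["group"] == "delay", "shift_ct"]
    a_vals = df.loc[df["group"] == "advance", "shift_ct"]
    groups = {"delay": _group_stats(d_vals), "advance": _group_stats(a_vals)}
    if groups["delay"]["n"] >= 2 and groups["advance"]["n"] >= 2:
        tstat, pval = stats.ttest_ind(d_vals, a_vals)
    else:
        tstat, pval = np.nan, np.nan
    # display polynomial on CT unwrapped at the delay-range start so the
    # fitted domain is contiguous
    ct_unwrapped = (df["onset_ct"].to_numpy() - lo) % 24.0
    coeffs = np.polyfit(ct_unwrapped, df["shift_ct"].to_numpy(),
                        min(poly_order, len(df) - 1))
    return {"table": df, "groups": groups, "t_stat": float(tstat),
            "p_value": float(pval), "poly_coeffs": coeffs,
            "poly_unwrap_origin_ct": lo}


def amplitude_response(before_fit: CosinorResults, after_pulse_fit: CosinorResults,
                       raw_before, raw_after) -> float:
    """Relative-amplitude fold change across a single stimulus."""
    from .cosinor import relative_amplitude
    ra_before = relative_amplitude(before_fit, raw_before)
    if ra_before <= 0:
        raise ValueError("Before relative amplitude must be positive")
    return relative_amplitude(after_pulse_fit, raw_after) / ra_before


def phase_relationship_table(peaks_during: dict[str, PeakSet],
                             protocol: TemperatureProtocol,
                             tau_before_per_cell: dict[str, float],
                             n_last_cycles: int = 2) -> dict:
    """Per-cell lag between the last peaks and their cold onsets, vs period.

    For each cell the signed lag (hours) between each of the last
    ``n_last_cycles`` cold-phase onsets and the nearest During peak is
    averaged; an OLS regression of that lag on the cell's free-running
    period tests whether the phase relationship depends on the intrinsic
    period.  Cells with a missing peak for one of the cycles are dropped
    and listed under ``dropped``.
    """
    onsets = protocol.cold_onsets()[-n_last_cycles:]
    rows, dropped = [], []
    for cell, peaks in peaks_during.items():
        if cell not in tau_before_per_cell:
            dropped.append({"cell_id": cell, "reason": "no Before period"})
            continue
        lags = []
        for onset in onsets:
            pk = peaks.in_window(protocol.start_h, protocol.end_h)
            if len(pk) == 0:
                break
            d = pk - onset
            j = int(np.argmin(np.abs(d)))
            if abs(d[j]) > protocol.cycle_length_h / 2.0:
                break
            lags.append(float(d[j]))
        if len(lags) < n_last_cycles:
            dropped.append({"cell_id": cell, "reason": "missing peak in last cycles"})
            continue
        rows.append({"cell_id": cell, "lag_h": float(np.mean(lags)),
                     "tau_before_h": tau_before_per_cell[cell]})
    table = pd.DataFrame(rows)
    if len(table) >= 3:
        reg = stats.linregress(table["tau_before_h"], table["lag_h"])
        slope, r2, p = float(reg.slope), float(reg.rvalue ** 2), float(reg.pvalue)
    else:
        slope = r2 = p = np.nan
    return {"table": table, "slope": slope, "r_squared": r2, "p_value": p,
            "dropped": dropped}
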