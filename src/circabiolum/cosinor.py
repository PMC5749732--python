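"""Cosine (single-component cosinor) fitting of circadian segments.

The model is

    b(t) = a * cos(2*pi*t/tau - theta) + offset

with amplitude ``a`` (gray levels), period ``tau`` (hours), acrophase
parameter ``theta`` (radians) and a vertical ``offset``.  Periods are
estimated by nonlinear least squares seeded with a fast-Fourier-transform
initial guess restricted to the circadian band (18-30 h); only fits with
18 <= tau <= 30 h (inclusive) pass the circadian filter.  The public
surface follows the Model/Results convention: build a :class:`CosinorModel`
from a segment, call :meth:`~CosinorModel.fit`, and read estimates,
standard errors and diagnostics off the returned :class:`CosinorResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import NoRhythmError
from .traces import Trace

__all__ = [
    "CosinorModel",
    "CosinorResults",
    "CosineFit",
    "fft_initial_guess",
    "fit_cosine",
    "circadian_filter",
    "relative_amplitude",
    "period_summary",
    "CIRCADIAN_BAND_H",
]

CIRCADIAN_BAND_H = (18.0, 30.0)


def _cosine(t, a, tau, theta, offset):
    return a * np.cos(2.0 * np.pi * t / tau - theta) + offset


def _as_time_values(segment) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(segment, Trace):
        return segment.time_h, segment.values
    t, v = segment
    return np.asarray(t, dtype=float), np.asarray(v, dtype=float)


def fft_initial_guess(segment, band_h: tuple[float, float] = CIRCADIAN_BAND_H):
    """FFT-based starting values ``(a0, tau0, theta0, offset0, low_power)``.

    The period guess is the inverse of the frequency of the largest
    periodogram peak within the circadian band (default 1/30 to 1/18 per
    hour); amplitude and phase come from projecting the mean-removed data
    onto the cosine/sine pair at that frequency, the offset from the segment
    mean.  ``low_power`` flags a guess whose band peak does not rise above
    twice the mean off-DC spectral power (e.g. white noise); callers may
    treat such fits with suspicion but fitting still proceeds.

    Raises
    ------
    NoRhythmError
        If the record is too short to place any Fourier bin inside the band.
    """
    t, v = _as_time_values(segment)
    n = len(v)
    if n < 4:
        raise NoRhythmError("segment too short for a spectral guess")
    dt = t[1] - t[0]
    demeaned = v - v.mean()
    power = np.abs(np.fft.rfft(demeaned)) ** 2
    freqs = np.fft.rfftfreq(n, d=dt)
    lo, hi = 1.0 / band_h[1], 1.0 / band_h[0]
    in_band = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_band):
        raise NoRhythmError(
            f"no Fourier bin in the {band_h[0]}-{band_h[1]} h band "
            f"(record length {n * dt:.1f} h)")
    band_idx = np.flatnonzero(in_band)
    k = band_idx[np.argmax(power[band_idx])]
    tau0 = 1.0 / freqs[k]
    omega = 2.0 * np.pi * freqs[k]
    # project onto cos/sin at the peak frequency, on the absolute time axis,
    # so theta0 is already in the model's convention
    c = demeaned @ np.cos(omega * t)
    s = demeaned @ np.sin(omega * t)
    a0 = 2.0 * np.hypot(c, s) / n
    theta0 = float(np.arctan2(s, c) % (2.0 * np.pi))
    low_power = power[k] < 2.0 * power[1:].mean() if n > 2 else True
    return a0, float(tau0), theta0, float(v.mean()), bool(low_power)


@dataclass
class CosinorResults:
    """Estimates and diagnostics of one cosine fit.

    Attributes
    ----------
    amplitude, period_h, theta_rad, offset : float
        Canonicalised estimates (amplitude >= 0, theta in [0, 2*pi)).
    bse : ndarray or None
        Asymptotic standard errors (a, tau, theta, offset) from the
        Gauss-Newton covariance; None for degenerate fits.
    rss : float
        Residual sum of squares at the optimum.
    converged : bool
    low_power : bool
        Spectral seed flag (see :func:`fft_initial_guess`).
    """

    amplitude: float
    period_h: float
    theta_rad: float
    offset: float
    rss: float
    nobs: int
    converged: bool
    low_power: bool = False
    bse: np.ndarray | None = None
    segment_label: str = ""
    cell_id: str = ""

    # short aliases matching the field's symbols
    @property
    def a(self) -> float:
        return self.amplitude

    @property
    def tau(self) -> float:
        return self.period_h

    @property
    def theta(self) -> float:
        return self.theta_rad

    @property
    def params(self) -> np.ndarray:
        return np.array([self.amplitude, self.period_h, self.theta_rad, self.offset])

    def predict(self, t_h) -> np.ndarray:
        return _cosine(np.asarray(t_h, dtype=float), *self.params)

    def peak_time_after(self, t_h: float) -> float:
        """First time >= ``t_h`` at which the fitted cosine is maximal."""
        period_starts = self.period_h * self.theta_rad / (2.0 * np.pi)
        k = np.ceil((t_h - period_starts) / self.period_h)
        return float(period_starts + k * self.period_h)

    def summary(self) -> str:
        lines = [
            "Cosinor fit" + (f" [{self.cell_id} {self.segment_label}]".rstrip() if
                             (self.cell_id or self.segment_label) else ""),
            "=" * 44,
            f"{'n obs':<22}{self.nobs:>22}",
            f"{'converged':<22}{str(self.converged):>22}",
            f"{'low spectral power':<22}{str(self.low_power):>22}",
        ]
        names = ["amplitude (gray)", "period (h)", "theta (rad)", "offset (gray)"]
        for i, (name, val) in enumerate(zip(names, self.params)):
            se = f"{self.bse[i]:.4g}" if self.bse is not None else "--"
            lines.append(f"{name:<22}{val:>12.4f}  se {se:>8}")
        lines.append(f"{'RSS':<22}{self.rss:>22.6g}")
        return "\n".join(lines)


# Backwards-compatible name used throughout the pipeline tables.
CosineFit = CosinorResults


class CosinorModel:
    """Nonlinear least-squares cosine model for one trace segment.

    Parameters
    ----------
    endog : array-like
        Processed gray values.
    exog_time_h : array-like
        Sample times in hours (uniform grid).
    """

    #: relative-RSS convergence tolerance and iteration cap of the optimiser
    ftol = 1e-8
    max_iter = 500

    def __init__(self, endog, exog_time_h, cell_id: str = "", segment_label: str = ""):
        self.endog = np.asarray(endog, dtype=float)
        self.time_h = np.asarray(exog_time_h, dtype=float)
        if self.endog.shape != self.time_h.shape:
            raise ValueError("endog and time must have equal length")
        self.cell_id = cell_id
        self.segment_label = segment_label

    @classmethod
    def from_trace(cls, trace: Trace, segment_label: str = "") -> "CosinorModel":
        return cls(trace.values, trace.time_h, cell_id=trace.cell_id,
                   segment_label=segment_label)

    def _degenerate(self, low_power: bool) -> CosinorResults:
        offset = float(self.endog.mean()) if len(self.endog) else np.nan
        rss = float(np.sum((self.endog - offset) ** 2))
        warnings.warn("degenerate (constant or arrhythmic) segment: amplitude fixed at 0")
        return CosinorResults(0.0, np.nan, 0.0, offset, rss, len(self.endog),
                              converged=True, low_power=low_power,
                              cell_id=self.cell_id, segment_label=self.segment_label)

    def fit(self, start_params=None) -> CosinorResults:
        """Fit by least squares; FFT-seeded unless ``start_params`` is given.

        Non-convergence is reported on the results object (``converged``),
        never raised; a constant segment yields an amplitude-zero fit with a
        warning.
        """
        t, v = self.time_h, self.endog
        if len(v) < 8:
            raise ValueError("need at least 8 samples to fit four parameters")
        low_power = False
        if start_params is None:
            if np.ptp(v) == 0:
                return self._degenerate(low_power=True)
            try:
                a0, tau0, th0, off0, low_power = fft_initial_guess((t, v))
            except NoRhythmError:
                raise
            start_params = (a0, tau0, th0, off0)
        p0 = np.asarray(start_params, dtype=float)
        if not np.all(np.isfinite(p0)):
            raise ValueError("start parameters must be finite")
        if p0[0] == 0:
            return self._degenerate(low_power=low_power)

        def resid(p):
            return _cosine(t, *p) - v

        sol = optimize.least_squares(resid, p0, method="lm", ftol=self.ftol,
                                     xtol=1e-12, gtol=1e-12,
                                     max_nfev=self.max_iter * 5)
        a, tau, theta, offset = sol.x
        tau = abs(tau)
        if a < 0:  # canonical form: non-negative amplitude
            a, theta = -a, theta + np.pi
        theta = float(theta % (2.0 * np.pi))
        rss = float(2.0 * sol.cost)
        bse = None
        dof = len(v) - 4
        if dof > 0 and sol.jac is not None:
            jtj = sol.jac.T @ sol.jac
            try:
                cov = np.linalg.inv(jtj) * (rss / dof)
                bse = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                bse = None
        return CosinorResults(float(a), float(tau), theta, float(offset), rss,
                              len(v), converged=bool(sol.success),
                              low_power=low_power, bse=bse,
                              cell_id=self.cell_id, segment_label=self.segment_label)


def fit_cosine(segment, init=None, segment_label: str = "") -> CosinorResults:
    """Functional wrapper: fit the cosine model to a segment.

    ``segment`` is a :class:`~circabiolum.traces.Trace` or a ``(time, values)``
    pair; ``init`` optional ``(a0, tau0, theta0, offset0)``.
    """
    t, v = _as_time_values(segment)
    cell = segment.cell_id if isinstance(segment, Trace) else ""
    model = CosinorModel(v, t, cell_id=cell, segment_label=segment_label)
    return model.fit(start_params=init)


def circadian_filter(fit: CosinorResults,
                     band_h: tuple[float, float] = CIRCADIAN_BAND_H) -> bool:
    """Accept a fit iff its period lies in [18, 30] h (inclusive) and it converged."""
    if not fit.converged or not np.isfinite(fit.period_h):
        return False
    return band_h[0] <= fit.period_h <= band_h[1]


def relative_amplitude(fit: CosinorResults, raw_segment) -> float:
    """Fitted amplitude divided by the mean of the *unprocessed* segment."""
    if isinstance(raw_segment, Trace):
        raw = raw_segment.values
    elif isinstance(raw_segment, tuple):
        raw = np.asarray(raw_segment[1], dtype=float)
    else:
        raw = np.asarray(raw_segment, dtype=float)
    mean_raw = float(np.mean(raw))
    if mean_raw <= 0:
        raise ValueError("mean of the unprocessed segment must be positive")
    return fit.amplitude / mean_raw


def period_summary(fits_by_stage: dict[str, list], paired: bool = False):
    """Mean, SD and coefficient of variation of accepted periods per stage.

    ``fits_by_stage`` maps a stage label to a list of :class:`CosinorResults`
    (or bare periods).  CV = SD/mean * 100 %.  Stages with fewer than two
    accepted periods get ``cv = nan`` and ``cv_defined = False``.  With
    ``paired=True`` only cells present in every stage enter (repeated-
    measures layout); the fits must then carry ``cell_id``.
    """
    import pandas as pd

    def _tau(f):
        return f.period_h if isinstance(f, CosinorResults) else float(f)

    def _cell(f):
        return f.cell_id if isinstance(f, CosinorResults) else None

    stage_taus: dict[str, dict] = {}
    for stage, fits in fits_by_stage.items():
        stage_taus[stage] = {(_cell(f) or i): _tau(f) for i, f in enumerate(fits)}
    if paired:
        common = set.intersection(*(set(d) for d in stage_taus.values()))
        stage_taus = {s: {c: d[c] for c in common} for s, d in stage_taus.items()}
    rows = []
    for stage, d in stage_taus.items():
        taus = np.array(list(d.values()), dtype=float)
        n = len(taus)
        mean = taus.mean() if n else np.nan
        sd = taus.std(ddof=1) if n >= 2 else np.nan
        cv = 100.0 * sd / mean if n >= 2 and mean else np.nan
        rows.append({"stage": stage, "n": n, "mean_h": mean, "sd_h": sd,
                     "cv_percent": cv, "cv_defined": n >= 2})
    return pd.DataFrame(rows)
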