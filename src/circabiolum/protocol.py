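"""Square-wave temperature protocols (zeitgeber definition).

A temperature cycle of length ``T`` hours consists of a cold phase followed by
a warm phase, repeated ``n_cycles`` times starting at ``start_h`` hours into
the recording.  Outside the cycling window the incubation temperature is held
at the warm level, matching the constant-condition segments of a T-cycle
experiment.  The protocol partitions a recording into the three analysis
stages *Before*, *During* and *After*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidProtocolError

__all__ = ["TemperatureProtocol", "make_protocol"]

STAGES = ("before", "during", "after")


@dataclass(frozen=True)
class TemperatureProtocol:
    """A repeated cold/warm square-wave temperature cycle.

    Parameters
    ----------
    cycle_length_h : float
        Zeitgeber period T in hours (e.g. 20 for a T20 cycle).
    cold_h, warm_h : float
        Durations of the cold and warm phase; each cycle starts cold.
    temp_cold, temp_warm : float
        Plateau temperatures in °C.
    n_cycles : int
        Number of cycle repeats (the canonical paradigms use six).
    start_h : float
        Hours from the start of the recording to the first cold onset.
    """

    cycle_length_h: float
    cold_h: float
    warm_h: float
    temp_cold: float
    temp_warm: float
    n_cycles: int
    start_h: float = 0.0

    def __post_init__(self) -> None:
        if self.cold_h <= 0 or self.warm_h <= 0 or self.cycle_length_h <= 0:
            raise InvalidProtocolError("durations must be positive")
        if abs(self.cold_h + self.warm_h - self.cycle_length_h) > 1e-9:
            raise InvalidProtocolError("cold_h + warm_h must equal cycle_length_h")
        if self.n_cycles < 1:
            raise InvalidProtocolError("n_cycles must be >= 1")
        if not self.temp_cold < self.temp_warm:
            raise InvalidProtocolError("temp_cold must be below temp_warm")
        if self.start_h < 0:
            raise InvalidProtocolError("start_h must be non-negative")

    @property
    def delta_T(self) -> float:
        return self.temp_warm - self.temp_cold

    @property
    def end_h(self) -> float:
        """End of the cycling window (start of *After*)."""
        return self.start_h + self.n_cycles * self.cycle_length_h

    def temperature_at(self, t_h):
        """Temperature (°C) at time(s) ``t_h``; warm outside the cycles."""
        t = np.asarray(t_h, dtype=float)
        phase = (t - self.start_h) % self.cycle_length_h
        in_cycles = (t >= self.start_h) & (t < self.end_h)
        cold = in_cycles & (phase < self.cold_h)
        out = np.where(cold, self.temp_cold, self.temp_warm)
        return out if out.ndim else float(out)

    def cold_onsets(self) -> np.ndarray:
        """Absolute times (h) at which each cold phase begins."""
        return self.start_h + np.arange(self.n_cycles) * self.cycle_length_h

    def cold_ends(self) -> np.ndarray:
        return self.cold_onsets() + self.cold_h

    def stage_of(self, t_h):
        """Stage label ('before'/'during'/'after') for time(s) ``t_h``."""
        t = np.asarray(t_h, dtype=float)
        lab = np.where(t < self.start_h, "before",
                       np.where(t < self.end_h, "during", "after"))
        return lab if lab.ndim else str(lab)

    def last_cycles_window(self, k: int = 3) -> tuple[float, float]:
        """Time window [lo, hi) covering the last ``k`` cycles of *During*."""
        k = min(k, self.n_cycles)
        return self.end_h - k * self.cycle_length_h, self.end_h

    def to_dict(self) -> dict:
        return {
            "cycle_length_h": self.cycle_length_h,
            "cold_h": self.cold_h,
            "warm_h": self.warm_h,
            "temp_cold": self.temp_cold,
            "temp_warm": self.temp_warm,
            "n_cycles": self.n_cycles,
            "start_h": self.start_h,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemperatureProtocol":
        return cls(**d)


def make_protocol(cycle_length_h: float, cold_h: float, delta_T: float,
                  n_cycles: int, start_h: float = 72.0,
                  temp_warm: float = 37.0) -> TemperatureProtocol:
    """Build a protocol from the quantities an experimenter states.

    ``make_protocol(20, 10, 4, 6, 72)`` is the fibroblast T20 paradigm
    (six repeats of 10 h at 33 °C / 10 h at 37 °C); ``(24, 12, 4, 6, 72)``
    the T24 one; ``(20, 10, 2, ...)`` the SCN-dispersal variant with a
    2 °C amplitude.
    """
    if cycle_length_h <= 0 or cold_h <= 0 or delta_T <= 0:
        raise InvalidProtocolError("cycle length, cold duration and delta_T must be positive")
    if cold_h >= cycle_length_h:
        raise InvalidProtocolError("cold_h must be shorter than the cycle")
    return TemperatureProtocol(
        cycle_length_h=float(cycle_length_h),
        cold_h=float(cold_h),
        warm_h=float(cycle_length_h - cold_h),
        temp_cold=float(temp_warm - delta_T),
        temp_warm=float(temp_warm),
        n_cycles=int(n_cycles),
        start_h=float(start_h),
    )
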