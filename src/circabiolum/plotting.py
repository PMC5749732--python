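"""Static figures: polar phase plots and response curves."""

from __future__ import annotations

import numpy as np

from . import circstats as cs


def polar_phase_plot(ct_hours, ax=None, label: str = "", color: str = "C1"):
    """Peak phases on a 24-h clock face with the mean-direction arrow.

    The arrow's length is the resultant length R; it crosses the unit circle
    only for strongly clustered samples, mirroring the usual significance
    visualisation.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ang = cs.ct_to_angle(ct_hours)
    ax.plot(ang, np.ones_like(ang), "o", mfc="none", color="k")
    mean_ang, rbar = cs.mean_direction(ang)
    if np.isfinite(mean_ang):
        ax.annotate("", xy=(mean_ang, rbar), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="-|>", color=color, lw=2))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_xticks(np.arange(0, 2 * np.pi, np.pi / 6))
    ax.set_xticklabels([f"{h}" for h in range(0, 24, 2)])
    ax.set_yticklabels([])
    ax.set_ylim(0, 1.15)
    if label:
        ax.set_title(label)
    return ax


def prc_plot(prc: dict, ax=None, ylabel: str = "phase shift (CT h)"):
    """Scatter of shifts vs stimulus-onset CT with the display polynomial."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    table = prc["table"]
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.plot(table["onset_ct"], table["shift_ct"], "ko", mfc="none")
    lo = prc["poly_unwrap_origin_ct"]
    grid = np.linspace(0.0, 24.0, 241)
    fit = np.polyval(prc["poly_coeffs"], grid)
    ax.plot((grid + lo) % 24.0, fit, ".", ms=2, color="C0")
    ax.set_xlabel("circadian time of stimulus onset (CT h)")
    ax.set_ylabel(ylabel)
    ax.set_xlim(0, 24)
    return ax
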