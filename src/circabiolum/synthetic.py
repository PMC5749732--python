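"""Ground-truthed synthetic single-cell circadian data.

The generator stands in for unavailable single-cell bioluminescence
recordings.  Each cell is a stochastic Poincare (amplitude-phase) oscillator
integrated by Euler-Maruyama,

    dx = [ -omega_i * y + lam * x * (A - r) + K * (x_mean - x) + Fx ] dt + sigma dW
    dy = [  omega_i * x + lam * y * (A - r) + K * (y_mean - y) + Fy ] dt + sigma dW

with radius r = sqrt(x^2 + y^2), intrinsic frequency omega_i = 2*pi/tau_i,
radial relaxation rate ``lam`` toward the limit-cycle amplitude ``A``, and
all-to-all mean-field coupling of strength ``K``.  Temperature forces the
oscillator through the zero-mean square-wave drive z(t) =
(temperature - cycle midpoint)/delta_T, i.e. -1/2 in the cold phase and +1/2
in the warm phase of the cycling window and 0 under constant temperature, so
Before/After segments are genuinely unforced.  In the default
``forcing_mode='tangential'`` the force is a pure phase kick of magnitude
``eps * z * sin(beta - phi)`` along the local tangent, the classical
phase-sensitivity (infinitesimal PRC) formulation: cold pulses delivered in
mid subjective day (about CT6-CT18) delay the clock and advance it
otherwise, matching the biphasic cold-pulse response of fibroblasts, while
rhythm amplitude is left untouched, matching their flat amplitude-response
curve.  ``forcing_mode='vector'`` instead applies the constant force
``eps * z * (ux, uy)``, which adds amplitude effects.  The sensitivity
direction beta comes from ``forcing_dir``.  Intrinsic periods are drawn
from a normal distribution truncated to the circadian band.

The observable emulates a damped PER2::LUC bioluminescence signal in camera
gray values,

    b(t) = baseline0 * 2**(-t/halflife) * (1 + (x + A)/(2A)) + N(0, noise_obs_sd),

sampled every 0.5 h (the 30-min camera exposure).  Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import TemperatureProtocol
from .traces import Trace

__all__ = ["OscillatorParams", "SimulatedCell", "simulate_population", "render_movie"]

#: observation grid fixed at the camera exposure (hours)
DT_OBS_H = 0.5


@dataclass
class OscillatorParams:
    """Parameters of the synthetic oscillator population.

    Units: periods/durations in hours, rates in 1/h, ``forcing_eps`` in
    amplitude units per hour per unit drive, noise in gray levels
    (``noise_obs_sd``) or limit-cycle-radius units per sqrt-hour
    (``noise_phase_sd``).
    """

    tau_mean: float = 24.0
    tau_sd: float = 1.5
    lambda_relax: float = 0.1
    amp_target: float = 1.0
    forcing_eps: float = 0.6
    coupling_K: float = 0.0
    noise_phase_sd: float = 0.05
    noise_obs_sd: float = 2.0
    baseline0: float = 150.0
    damping_halflife_h: float = 72.0
    forcing_dir: tuple[float, float] = (0.4536, 0.8912)  # angle 1.1 rad
    forcing_mode: str = "tangential"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 18.0 <= self.tau_mean <= 30.0:
            raise ValueError("tau_mean must lie in the circadian band [18, 30] h")
        for name in ("tau_sd", "lambda_relax", "forcing_eps", "coupling_K",
                     "noise_phase_sd", "noise_obs_sd", "damping_halflife_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.amp_target <= 0:
            raise ValueError("amp_target must be positive")
        if self.forcing_mode not in ("tangential", "vector"):
            raise ValueError("forcing_mode must be 'tangential' or 'vector'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["forcing_dir"] = list(self.forcing_dir)
        return d


@dataclass
class SimulatedCell:
    """One simulated cell: observed trace plus its ground truth."""

    trace: Trace
    true_tau: float
    true_phase_series: np.ndarray  # unwrapped phase (rad) on the trace's grid
    true_position_series: np.ndarray | None = None  # (n_frames, 2) row/col

    def true_peak_times(self) -> np.ndarray:
        """Times (h) at which the noiseless oscillation peaks (phase = 0 mod 2*pi).

        Found by linear interpolation of the unwrapped phase through integer
        multiples of 2*pi.
        """
        phi = self.true_phase_series
        t = self.trace.time_h
        k_lo = int(np.ceil(phi[0] / (2 * np.pi)))
        k_hi = int(np.floor(phi[-1] / (2 * np.pi)))
        out = []
        for k in range(k_lo, k_hi + 1):
            target = 2 * np.pi * k
            j = int(np.searchsorted(phi, target))
            if j == 0 or j >= len(phi):
                continue
            f = (target - phi[j - 1]) / (phi[j] - phi[j - 1])
            out.append(t[j - 1] + f * (t[j] - t[j - 1]))
        return np.asarray(out)


def _draw_truncated_periods(rng, n, mean, sd, lo=18.0, hi=30.0):
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_population(n_cells: int, params: OscillatorParams,
                        protocol: TemperatureProtocol | None = None,
                        duration_h: float = 240.0, dt_h: float = 0.05,
                        initial_phases: np.ndarray | None = None) -> list[SimulatedCell]:
    """Integrate a coupled, forced oscillator population (Euler-Maruyama).

    ``protocol`` may be None for constant-temperature (free-running) runs.
    Initial phases are uniform on the circle unless given; initial radius is
    the limit-cycle amplitude.  Observation samples are taken every 0.5 h.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if dt_h > 0.1:
        raise ValueError("integration step too coarse (dt_h must be <= 0.1)")
    if protocol is not None and protocol.end_h > duration_h + 1e-9:
        raise ValueError("duration_h must cover the protocol")
    rng = np.random.default_rng(params.seed)
    tau = _draw_truncated_periods(rng, n_cells, params.tau_mean, params.tau_sd)
    omega = 2.0 * np.pi / tau
    A = params.amp_target
    if initial_phases is None:
        initial_phases = rng.uniform(0.0, 2.0 * np.pi, size=n_cells)
    x = A * np.cos(initial_phases)
    y = A * np.sin(initial_phases)

    n_steps = int(round(duration_h / dt_h))
    obs_every = int(round(DT_OBS_H / dt_h))
    n_obs = n_steps // obs_every + 1
    xs = np.empty((n_obs, n_cells))
    ys = np.empty((n_obs, n_cells))
    xs[0], ys[0] = x, y

    ux, uy = params.forcing_dir
    norm = np.hypot(ux, uy)
    if norm > 0:
        ux, uy = ux / norm, uy / norm
    sqdt = np.sqrt(dt_h)
    sigma = params.noise_phase_sd * A
    lam, K, eps = params.lambda_relax, params.coupling_K, params.forcing_eps
    i_obs = 1
    for step in range(1, n_steps + 1):
        t = (step - 1) * dt_h
        if protocol is not None and eps > 0 and \
                protocol.start_h <= t < protocol.end_h:
            # normalized square-wave drive, zero-mean across one cycle:
            # -1/2 in cold, +1/2 in warm; no drive outside the cycling window
            midpoint = 0.5 * (protocol.temp_cold + protocol.temp_warm)
            z = (float(protocol.temperature_at(t)) - midpoint) / protocol.delta_T
        else:
            z = 0.0
        r = np.hypot(x, y)
        relax = lam * (A - r)
        if z != 0.0:
            if params.forcing_mode == "tangential":
                # phase-sensitivity forcing: magnitude eps*z*sin(beta - phi)
                # along the tangent (-sin phi, cos phi); pure phase response,
                # no radial (amplitude) kick
                rs = np.where(r > 1e-12, r, 1.0)
                sens = (uy * x - ux * y) / rs  # sin(beta - phi)
                fx = -eps * z * sens * y / rs
                fy = eps * z * sens * x / rs
            else:
                fx = eps * z * ux
                fy = eps * z * uy
        else:
            fx = fy = 0.0
        xm, ym = x.mean(), y.mean()
        dx = (-omega * y + x * relax + K * (xm - x) + fx) * dt_h
        dy = (omega * x + y * relax + K * (ym - y) + fy) * dt_h
        if sigma > 0:
            dx = dx + sigma * sqdt * rng.standard_normal(n_cells)
            dy = dy + sigma * sqdt * rng.standard_normal(n_cells)
        x = x + dx
        y = y + dy
        if step % obs_every == 0:
            xs[i_obs], ys[i_obs] = x, y
            i_obs += 1
    if not np.all(np.isfinite(xs)):
        raise FloatingPointError("integration diverged; decrease dt_h or rates")

    t_obs = np.arange(n_obs) * DT_OBS_H
    decay = params.baseline0 * np.power(2.0, -t_obs / params.damping_halflife_h)
    cells = []
    for i in range(n_cells):
        clean = decay * (1.0 + (xs[:, i] + A) / (2.0 * A))
        noisy = clean + rng.normal(0.0, params.noise_obs_sd, size=n_obs) \
            if params.noise_obs_sd > 0 else clean
        phi = np.unwrap(np.arctan2(ys[:, i], xs[:, i]))
        stage = None if protocol is None else protocol.stage_of(t_obs)
        tr = Trace(cell_id=f"cell{i:03d}", time_h=t_obs, values=noisy, stage=stage)
        cells.append(SimulatedCell(trace=tr, true_tau=float(tau[i]),
                                   true_phase_series=phi))
    return cells


def render_movie(cells: list[SimulatedCell], frame_shape_px: tuple[int, int] = (48, 48),
                 spot_sigma_px: float = 1.5, motility_sd_px: float = 0.0,
                 background_level: float = 10.0, noise_sd: float = 0.0,
                 hot_pixel_rate: float = 0.0, hot_value: float = 1000.0,
                 seed: int = 0, positions: np.ndarray | None = None):
    """Render cells as Gaussian spots into a bioluminescence movie.

    Each cell becomes an isotropic Gaussian whose *integrated* intensity per
    frame equals the cell's trace value at that frame; spot centres follow a
    reflected random walk (per-frame step sd ``motility_sd_px``).  Additive
    Gaussian background noise and salt-type hot pixels (probability
    ``hot_pixel_rate`` per pixel per frame, value ``hot_value``) emulate
    camera artefacts.  Returns ``(ImageStack, truth)`` where ``truth`` is a
    tidy DataFrame (frame, cell_id, row, col) of the true positions, which
    are also attached to each cell's ``true_position_series``.
    """
    from .imaging import ImageStack

    h, w = frame_shape_px
    n_frames = len(cells[0].trace.time_h)
    n_cells = len(cells)
    rng = np.random.default_rng(seed)
    margin = max(3.0 * spot_sigma_px, 3.0)
    if margin * 2 >= min(h, w):
        raise ValueError("spots do not fit inside the frame")
    if positions is None:
        grid = int(np.ceil(np.sqrt(n_cells)))
        rr = np.linspace(margin, h - 1 - margin, grid)
        cc = np.linspace(margin, w - 1 - margin, grid)
        pts = np.array([(r, c) for r in rr for c in cc])[:n_cells]
        positions = np.round(pts)
    pos = np.asarray(positions, dtype=float).copy()

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    frames = np.empty((n_frames, h, w))
    track = np.empty((n_frames, n_cells, 2))
    two_sig2 = 2.0 * spot_sigma_px ** 2
    norm = 2.0 * np.pi * spot_sigma_px ** 2
    overlap_frame = None
    for f in range(n_frames):
        if f > 0 and motility_sd_px > 0:
            pos += rng.normal(0.0, motility_sd_px, size=pos.shape)
            # reflect off the margins
            pos[:, 0] = np.abs(pos[:, 0] - margin) + margin
            pos[:, 0] = np.where(pos[:, 0] > h - 1 - margin,
                                 2 * (h - 1 - margin) - pos[:, 0], pos[:, 0])
            pos[:, 1] = np.abs(pos[:, 1] - margin) + margin
            pos[:, 1] = np.where(pos[:, 1] > w - 1 - margin,
                                 2 * (w - 1 - margin) - pos[:, 1], pos[:, 1])
        track[f] = pos
        img = np.full((h, w), float(background_level))
        for i, cell in enumerate(cells):
            amp = max(cell.trace.values[f], 0.0) / norm
            d2 = (rows - pos[i, 0]) ** 2 + (cols - pos[i, 1]) ** 2
            img += amp * np.exp(-d2 / two_sig2)
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=img.shape)
        if hot_pixel_rate > 0:
            hot = rng.random(img.shape) < hot_pixel_rate
            img[hot] = hot_value
        frames[f] = np.clip(img, 0.0, None)
        if n_cells > 1 and overlap_frame is None:
            d = np.hypot(pos[:, 0][:, None] - pos[:, 0][None, :],
                         pos[:, 1][:, None] - pos[:, 1][None, :])
            np.fill_diagonal(d, np.inf)
            if np.any(d < 2.0 * spot_sigma_px):
                overlap_frame = f
    if overlap_frame is not None:
        warnings.warn(f"overlapping spots (first in frame {overlap_frame})")

    for i, cell in enumerate(cells):
        cell.true_position_series = track[:, i, :].copy()
    truth = pd.DataFrame({
        "frame": np.repeat(np.arange(n_frames), n_cells),
        "cell_id": [c.trace.cell_id for _ in range(n_frames) for c in cells],
        "row": track[:, :, 0].ravel(),
        "col": track[:, :, 1].ravel(),
    })
    dt = float(cells[0].trace.time_h[1] - cells[0].trace.time_h[0])
    return ImageStack(frames=frames, dt_h=dt), truth
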