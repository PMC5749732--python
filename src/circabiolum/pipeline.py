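"""End-to-end orchestration: traces -> QC -> fits -> peaks -> phases -> stats.

The experiment-level surface follows the Model/Results convention:
:class:`TemperatureCycleExperiment` is built from per-cell traces plus a
temperature protocol, its :meth:`~TemperatureCycleExperiment.fit` runs the
whole analysis chain and returns an :class:`ExperimentResults` bundle with
tidy tables, circular statistics and a ``summary()``.  ``run_pipeline``
wraps this for configuration-file / CLI use and writes deterministic output
files (byte-identical for identical config + seed).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circstats as cs
from . import phase as ph
from .cosinor import (circadian_filter, fit_cosine, period_summary,
                      relative_amplitude)
from .errors import NoRhythmError
from .imaging import viability_qc
from .protocol import TemperatureProtocol, make_protocol
from .synthetic import OscillatorParams, simulate_population
from .traces import Trace, detrend_running_average, normalize_max, segment

__all__ = [
    "RunConfig",
    "TemperatureCycleExperiment",
    "ExperimentResults",
    "run_pipeline",
    "demo_t20_config",
    "demo_t24_config",
    "pulse_response_experiment",
]

_STAGE_FIT_SEGMENTS = {"before": "before", "during": "during_last", "after": "after"}


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's stated values.

    30-min sampling, 24-h detrending window, 11-h peak smoothing, 30-point
    parabola, the 18-30 h circadian filter, last-3-cycles During fits and
    the +/-1 h entrainment tolerance.
    """

    protocol: dict = field(default_factory=lambda: dict(
        cycle_length_h=20.0, cold_h=10.0, delta_T=4.0, n_cycles=6, start_h=72.0))
    synthetic: dict = field(default_factory=lambda: dict(n_cells=20, duration_h=240.0))
    oscillator: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=lambda: dict(
        normalize=True, normalize_target=255.0, detrend_window_h=24.0))
    rhythms: dict = field(default_factory=lambda: dict(
        band_h=(18.0, 30.0), last_cycles=3))
    phase: dict = field(default_factory=lambda: dict(
        smooth_window_h=11.0, fit_points=30, entrainment_tol_h=1.0,
        ct_mode="division"))
    qc: dict = field(default_factory=lambda: dict(
        min_final_fraction=0.1, rhythm_window_h=48.0))
    seed: int = 0
    outdir: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        # outdir is deployment detail, not part of the scientific config
        d = {k: getattr(self, k) for k in (
            "protocol", "synthetic", "oscillator", "preprocess", "rhythms",
            "phase", "qc", "seed", "log_level")}
        d["rhythms"] = dict(d["rhythms"], band_h=list(d["rhythms"]["band_h"]))
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            base = getattr(cfg, key)
            if isinstance(base, dict) and isinstance(val, dict):
                base.update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def make_protocol(self) -> TemperatureProtocol:
        return make_protocol(**self.protocol)


@dataclass
class ExperimentResults:
    """Tables and statistics produced by one pipeline run."""

    fits: pd.DataFrame
    periods: pd.DataFrame
    peaks: pd.DataFrame
    circ: dict
    shifts: pd.DataFrame
    prc: dict | None
    qc: pd.DataFrame
    phase_relationship: dict | None
    config: RunConfig
    protocol: TemperatureProtocol

    def summary(self) -> str:
        lines = ["Temperature-cycle experiment", "=" * 60]
        prot = self.protocol
        lines.append(f"protocol: T{prot.cycle_length_h:g} "
                     f"({prot.cold_h:g} h {prot.temp_cold:g} C / "
                     f"{prot.warm_h:g} h {prot.temp_warm:g} C), "
                     f"{prot.n_cycles} cycles from {prot.start_h:g} h")
        kept = int((self.qc["keep"]).sum()) if len(self.qc) else 0
        lines.append(f"cells: {len(self.qc)} recorded, {kept} kept after QC")
        lines.append("")
        lines.append("periods (accepted cosine fits)")
        lines.append(self.periods.to_string(index=False,
                                            float_format=lambda x: f"{x:.2f}"))
        lines.append("")
        lines.append("peak-phase clustering (Rayleigh)")
        for stage, d in self.circ.items():
            if not d:
                continue
            lines.append(f"  {stage:>7}: n={d['n']:>3}  mean CT={d['mean_ct']:5.1f}  "
                         f"R={d['resultant_length']:.2f}  Z={d['Z']:.2f}  "
                         f"p={d['p']:.3g}")
        if len(self.shifts):
            lines.append("")
            lines.append(f"phase shifts (first cold stimulus): n={len(self.shifts)}, "
                         f"mean {self.shifts['shift_ct'].mean():+.2f} CT h")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write all tables as CSV/JSON; no timestamps, so runs are
        byte-reproducible."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.fits.to_csv(out / "fits.csv", index=False)
        self.periods.to_csv(out / "periods.csv", index=False)
        self.peaks.to_csv(out / "peaks.csv", index=False)
        self.shifts.to_csv(out / "shifts.csv", index=False)
        self.qc.to_csv(out / "qc.csv", index=False)
        if self.prc is not None:
            self.prc["table"].to_csv(out / "prc.csv", index=False)
        with open(out / "circstats.json", "w") as fh:
            json.dump(self.circ, fh, indent=2, sort_keys=True)
        log = {"config": self.config.to_dict(),
               "config_hash": self.config.config_hash(),
               "seed": self.config.seed}
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True, default=str)


class TemperatureCycleExperiment:
    """Analysis model for one imaging run: traces + protocol -> results.

    Parameters
    ----------
    traces : list of Trace
        Raw per-cell traces on the common recording grid.
    protocol : TemperatureProtocol
    config : RunConfig, optional
        Module parameter blocks; defaults are the study values.
    """

    def __init__(self, traces: list[Trace], protocol: TemperatureProtocol,
                 config: RunConfig | None = None):
        if not traces:
            raise ValueError("no input traces")
        self.traces = traces
        self.protocol = protocol
        self.config = config or RunConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, protocol: TemperatureProtocol,
                       config: RunConfig | None = None) -> "TemperatureCycleExperiment":
        from .traces import frame_to_traces
        return cls(frame_to_traces(df), protocol, config)

    # -- stages -------------------------------------------------------------

    def _preprocess(self, trace: Trace) -> Trace:
        p = self.config.preprocess
        out = trace
        if p.get("normalize", True):
            out = normalize_max(out, target=p.get("normalize_target", 255.0))
        out = detrend_running_average(out, window_h=p.get("detrend_window_h", 24.0))
        return out

    def fit(self) -> ExperimentResults:
        cfg = self.config
        prot = self.protocol
        qc_rows, fit_rows, peak_rows = [], [], []
        fits_by_stage: dict[str, list] = {"before": [], "during": [], "after": []}
        cts_by_stage: dict[str, list] = {"before": [], "during": [], "after": []}
        shifts: list[ph.PhaseShift] = []
        peaks_during: dict[str, ph.PeakSet] = {}
        tau_before: dict[str, float] = {}
        entrained: set[str] = set()

        for raw in self.traces:
            qc = viability_qc(raw, **cfg.qc)
            qc_rows.append({"cell_id": raw.cell_id, "keep": qc.keep,
                            "reason": qc.reason or ""})
            if not qc.keep:
                continue
            proc = self._preprocess(raw)
            segs = segment(proc, prot, last_cycles=cfg.rhythms.get("last_cycles", 3))
            raw_segs = segment(raw, prot, last_cycles=cfg.rhythms.get("last_cycles", 3))
            # the detrender flags its truncated-window margins; cosine fits
            # only see the interior
            edge = proc.meta.get("edge_affected_h", 0.0)
            lo_ok = proc.time_h[0] + edge
            hi_ok = proc.time_h[-1] - edge

            cell_fits = {}
            for stage, seg_name in _STAGE_FIT_SEGMENTS.items():
                seg = segs[seg_name]
                if len(seg.time_h):
                    hi_stage = hi_ok
                    if stage == "during":
                        # near release the running-mean trend estimate is
                        # increasingly dominated by post-release free run;
                        # stop the During fit 4 h short of the transition
                        hi_stage = min(hi_ok, prot.end_h - 4.0)
                    seg = seg.restrict(max(seg.time_h[0], lo_ok),
                                       min(seg.time_h[-1] + seg.dt_h, hi_stage))
                if len(seg.time_h) < 8:
                    continue
                try:
                    res = fit_cosine(seg, segment_label=stage)
                except (NoRhythmError, ValueError):
                    continue
                accepted = circadian_filter(res, tuple(cfg.rhythms.get(
                    "band_h", (18.0, 30.0))))
                rel_amp = np.nan
                raw_mean = float(np.mean(raw_segs[seg_name].values)) \
                    if len(raw_segs[seg_name].values) else np.nan
                if accepted and raw_mean > 0:
                    rel_amp = relative_amplitude(res, raw_segs[seg_name].values)
                fit_rows.append({
                    "cell_id": raw.cell_id, "stage": stage, "a": res.amplitude,
                    "tau": res.period_h, "theta_rad": res.theta_rad,
                    "offset": res.offset, "rss": res.rss,
                    "accepted": accepted, "rel_amplitude": rel_amp})
                if accepted:
                    cell_fits[stage] = res
                    fits_by_stage[stage].append(res)

            peaks = ph.pick_peaks(proc,
                                  smooth_window_h=cfg.phase.get("smooth_window_h", 11.0),
                                  fit_points=cfg.phase.get("fit_points", 30))
            stages = prot.stage_of(peaks.peak_times_h) if len(peaks) else []
            for pt, stg in zip(peaks.peak_times_h, stages):
                peak_rows.append({"cell_id": raw.cell_id, "stage": stg,
                                  "peak_time_h": pt})
            before_pk = peaks.in_window(0.0, prot.start_h)
            during_pk = peaks.in_window(prot.start_h, prot.end_h)
            after_pk = peaks.in_window(prot.end_h, np.inf)
            peaks_during[raw.cell_id] = peaks

            bf = cell_fits.get("before")
            ct_mode = cfg.phase.get("ct_mode", "division")
            if bf is not None:
                tau_before[raw.cell_id] = bf.period_h
                # population polar plots: common origin (recording start)
                if len(before_pk):
                    cts_by_stage["before"].append(ph.to_circadian_free_run(
                        before_pk[-1], bf.period_h, 0.0, ct_mode))
                if len(after_pk):
                    cts_by_stage["after"].append(ph.to_circadian_free_run(
                        after_pk[0], bf.period_h, 0.0, ct_mode))
            # Fig-2D-style analyses only admit cells locked to the cycle
            tol = cfg.phase.get("entrainment_tol_h", 1.0)
            if "during" in cell_fits and ph.entrainment_filter(
                    cell_fits["during"], prot, tol):
                entrained.add(raw.cell_id)
            # During phase: mean of the last two peaks, CT12 = cold end
            last2 = during_pk[-2:]
            if len(last2):
                cts = [ph.to_circadian_entrained(t, prot) for t in last2]
                ang = cs.ct_to_angle(cts)
                mean_ang, _ = cs.mean_direction(ang)
                if np.isfinite(mean_ang):
                    cts_by_stage["during"].append(float(cs.angle_to_ct(mean_ang)))
            # single-stimulus phase shift (first cold phase)
            if bf is not None and len(before_pk) and len(during_pk):
                try:
                    exp_pk = ph.expected_peak(bf, prot.start_h)
                    act_pk = ph.match_actual_peak(exp_pk, ph.PeakSet(
                        raw.cell_id, during_pk, np.zeros(len(during_pk))),
                        bf.period_h)
                    shift = ph.phase_shift(exp_pk, act_pk, bf.period_h, ct_mode)
                    onset = ph.onset_ct(prot.start_h, before_pk, bf.period_h, ct_mode)
                    shifts.append(ph.PhaseShift(
                        raw.cell_id, exp_pk, act_pk, bf.period_h, shift, onset))
                except ValueError:
                    pass

        fits = pd.DataFrame(fit_rows)
        periods = period_summary(fits_by_stage)
        circ = {}
        for stage, cts in cts_by_stage.items():
            if not cts:
                circ[stage] = {}
                continue
            sample = cs.CircularSample.from_ct(cts, label=stage)
            mean_ang, rbar = cs.mean_direction(sample)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Z, p = cs.rayleigh_test(sample)
            circ[stage] = {"n": sample.n,
                           "mean_ct": float(cs.angle_to_ct(mean_ang))
                           if np.isfinite(mean_ang) else None,
                           "resultant_length": rbar, "Z": Z, "p": p}
        shift_df = pd.DataFrame(
            [{"cell_id": s.cell_id, "expected_peak_h": s.expected_peak_h,
              "actual_peak_h": s.actual_peak_h, "tau_before_h": s.tau_before_h,
              "shift_ct": s.shift_ct, "onset_ct": s.onset_ct} for s in shifts])
        prc = None
        if len(shifts) >= 3:
            prc = ph.build_prc(shifts)
        rel = None
        pk_entr = {c: p for c, p in peaks_during.items() if c in entrained}
        tb_entr = {c: t for c, t in tau_before.items() if c in entrained}
        if pk_entr and tb_entr:
            rel = ph.phase_relationship_table(pk_entr, prot, tb_entr)
        return ExperimentResults(
            fits=fits, periods=periods,
            peaks=pd.DataFrame(peak_rows), circ=circ, shifts=shift_df, prc=prc,
            qc=pd.DataFrame(qc_rows), phase_relationship=rel,
            config=cfg, protocol=prot)


def _synthesize(config: RunConfig) -> list[Trace]:
    params = OscillatorParams(**dict(config.oscillator, seed=config.seed))
    prot = config.make_protocol()
    cells = simulate_population(
        n_cells=int(config.synthetic.get("n_cells", 20)), params=params,
        protocol=prot, duration_h=float(config.synthetic.get("duration_h", 240.0)))
    return [c.trace for c in cells]


def run_pipeline(config: RunConfig, traces: list[Trace] | None = None) -> ExperimentResults:
    """Run the full chain; simulate input when no traces are supplied."""
    if traces is None:
        traces = _synthesize(config)
    if not traces:
        raise ValueError("empty input: no traces to analyse")
    exp = TemperatureCycleExperiment(traces, config.make_protocol(), config)
    results = exp.fit()
    if config.outdir:
        results.save(config.outdir)
    return results


def demo_t20_config(seed: int = 0, n_cells: int = 20) -> RunConfig:
    """Twenty synthetic fibroblasts under the strongly-forcing T20 paradigm."""
    cfg = RunConfig(seed=seed)
    cfg.protocol = dict(cycle_length_h=20.0, cold_h=10.0, delta_T=4.0,
                        n_cycles=6, start_h=72.0)
    cfg.synthetic = dict(n_cells=n_cells, duration_h=240.0)
    cfg.oscillator = dict(forcing_eps=0.6)
    return cfg


def demo_t24_config(seed: int = 0, n_cells: int = 200) -> RunConfig:
    """Same forcing, near-resonant T24 cycle: periods barely move."""
    cfg = demo_t20_config(seed=seed, n_cells=n_cells)
    cfg.protocol = dict(cycle_length_h=24.0, cold_h=12.0, delta_T=4.0,
                        n_cycles=6, start_h=72.0)
    return cfg


def pulse_response_experiment(n_cells: int = 40, seed: int = 0,
                              pulse_start_h: float = 72.0, cold_h: float = 10.0,
                              forcing_eps: float = 0.3,
                              oscillator_kwargs: dict | None = None,
                              duration_h: float = 192.0) -> dict:
    """Deliver one 10-h cold pulse per cell and assemble the PRC/ARC.

    Each cell starts at a random phase, so a single protocol samples stimulus
    onsets across the whole circadian cycle.  Returns the PRC dict of
    :func:`circabiolum.phase.build_prc` plus the shift and fold-change lists.
    """
    kwargs = dict(tau_mean=24.0, tau_sd=0.5, forcing_eps=forcing_eps,
                  noise_phase_sd=0.01, noise_obs_sd=1.0, seed=seed)
    kwargs.update(oscillator_kwargs or {})
    params = OscillatorParams(**kwargs)
    # one cycle whose warm half carries no drive = a clean single cold pulse
    prot = make_protocol(cycle_length_h=2 * cold_h, cold_h=cold_h, delta_T=4.0,
                         n_cycles=1, start_h=pulse_start_h)
    cells = simulate_population(n_cells, params, prot, duration_h=duration_h)
    shifts, folds = [], []
    for cell in cells:
        tr = detrend_running_average(cell.trace)
        edge = tr.meta.get("edge_affected_h", 0.0)
        before = tr.restrict(tr.time_h[0] + edge, pulse_start_h)
        after = tr.restrict(prot.end_h, duration_h - edge)
        raw_before = cell.trace.restrict(0.0, pulse_start_h)
        raw_after = cell.trace.restrict(prot.end_h, duration_h)
        try:
            bf = fit_cosine(before, segment_label="before")
            af = fit_cosine(after, segment_label="after")
        except NoRhythmError:
            continue
        if not (circadian_filter(bf) and circadian_filter(af)):
            continue
        peaks = ph.pick_peaks(tr)
        before_pk = peaks.in_window(0.0, pulse_start_h)
        post_pk = peaks.in_window(prot.start_h + cold_h, duration_h)
        if len(before_pk) == 0 or len(post_pk) == 0:
            continue
        try:
            exp_pk = ph.expected_peak(bf, prot.start_h + cold_h)
            act_pk = ph.match_actual_peak(exp_pk, ph.PeakSet(
                cell.trace.cell_id, post_pk, np.zeros(len(post_pk))), bf.period_h)
            shift = ph.phase_shift(exp_pk, act_pk, bf.period_h)
            onset = ph.onset_ct(prot.start_h, before_pk, bf.period_h)
        except ValueError:
            continue
        shifts.append(ph.PhaseShift(cell.trace.cell_id, exp_pk, act_pk,
                                    bf.period_h, shift, onset))
        folds.append(ph.amplitude_response(bf, af, raw_before.values,
                                           raw_after.values))
    prc = ph.build_prc(shifts, amp_folds=folds) if len(shifts) >= 3 else None
    return {"prc": prc, "shifts": shifts, "amp_folds": folds, "cells": cells}
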