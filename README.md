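# circabiolum

Quantitative analysis of **single-cell circadian bioluminescence under
temperature cycles**: from time-lapse image stacks (or pre-extracted trace
tables) to periods, phases, phase shifts, phase-/amplitude-response curves
and circular statistics — together with a ground-truthed synthetic generator
that emulates the recordings such experiments produce.

## The problem

Mammalian cells carry cell-autonomous circadian clocks that can be read out
as PER2::LUC bioluminescence.  Exposing cultured single cells (fibroblasts,
SCN neuron dispersals) to square-wave temperature cycles — e.g. a *T20*
cycle of 10 h at 33 °C followed by 10 h at 37 °C, repeated six times — asks
whether single cells entrain to the zeitgeber the way tissues do: do their
periods adopt the cycle length T, do their peak phases cluster, how does a
single 10-h cold pulse shift their phase as a function of the circadian time
at which it lands, and how does intercellular coupling modulate all of this?
Answering these questions from dim, noisy, motile single-cell recordings
requires a careful chain of image processing and rhythm analysis; this
package implements that chain as a tested, reusable library and CLI.

## The models at its core

**Rhythm estimation (cosinor).**  Each trace segment *Before*, *During* and
*After* the cycles is fitted by nonlinear least squares with

&nbsp;&nbsp;&nbsp;&nbsp; b(t) = a·cos(2π·t/τ − θ) + offset,

seeded by an FFT periodogram peak in the circadian band; only fits with
18 h ≤ τ ≤ 30 h are accepted, and During periods use the last three cycles
only.  `CosinorModel(endog, time).fit()` returns a `CosinorResults` with
estimates, asymptotic standard errors, residual diagnostics and a
`summary()`.

**Phases and responses.**  Peaks are picked by an 11-h running average plus
local parabola fits; circadian time is CT12 = end of cold during cycles and
CT18 = PER2::LUC peak in free run; the phase shift elicited by the first
cold stimulus is (expected − actual peak)·24/τ, negative for delays.  Phase
populations are summarised by the Rayleigh uniformity test (Z = nR̄²) and
compared by the Watson–Williams two-sample test.

**Synthetic ground truth.**  A population of stochastic Poincaré
(amplitude–phase) oscillators with heterogeneous intrinsic periods,
mean-field coupling, square-wave temperature drive and a damped
bioluminescence observation model stands in for the unavailable raw
recordings; a renderer turns simulated cells into multi-page TIFF movies
with motile Gaussian spots, camera noise and hot pixels for testing the
imaging chain (Kalman stack filter, median outlier removal, Viterbi-style
spot tracking, windowed extraction, viability QC).

## Worked example

```sh
circabiolum demo-t20 --seed 0 --outdir demo_out
```

runs the full pipeline on 20 simulated fibroblasts under the T20 paradigm
and prints

```
Temperature-cycle experiment
============================================================
protocol: T20 (10 h 33 C / 10 h 37 C), 6 cycles from 72 h
cells: 20 recorded, 20 kept after QC

periods (accepted cosine fits)
 stage  n  mean_h  sd_h  cv_percent  cv_defined
before 20   23.74  1.85        7.80        True
during 20   20.07  0.16        0.77        True
 after 20   24.03  2.01        8.35        True

peak-phase clustering (Rayleigh)
   before: n= 20  mean CT=  1.7  R=0.14  Z=0.38  p=0.691
   during: n= 20  mean CT= 15.8  R=0.98  Z=19.18  p=2.79e-13
    after: n= 20  mean CT=  9.2  R=0.13  Z=0.35  p=0.713
```

Free-running periods near 24 h shorten to the 20-h zeitgeber during the
cycles (with a collapse of the period coefficient of variation from ~8% to
~1%), peak phases go from uniform (Rayleigh p ≈ 0.7) to tightly clustered
(Z ≈ 19, p ≪ 0.001), and both revert after release — the signature of
temperature entrainment.  `demo_out/` contains the tidy tables (`fits.csv`,
`peaks.csv`, `shifts.csv`, `prc.csv`, `qc.csv`, `circstats.json`) plus a
`run_log.json` with the config hash; re-running with the same seed
reproduces every file byte for byte.

The same analysis is available programmatically:

```python
from circabiolum import TemperatureCycleExperiment, make_protocol
protocol = make_protocol(cycle_length_h=20, cold_h=10, delta_T=4,
                         n_cycles=6, start_h=72)
results = TemperatureCycleExperiment(traces, protocol).fit()
print(results.summary())
```

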