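# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `circabiolum`.  Nothing here states a number the test suite
or `scripts/acceptance.py` does not itself compute.

## Temperature protocols

A protocol is a square wave: `n_cycles` repeats of a cold phase (cold
first) followed by a warm phase, starting `start_h` hours into the
recording; outside the cycling window the temperature is held at the warm
(incubation) level.  The canonical paradigms are T20 (10 h at 33 °C / 10 h
at 37 °C), T24 (12 h / 12 h) and the 2 °C SCN variant.  The protocol
partitions a recording into *Before* `[0, start)`, *During*
`[start, start + n·T)` and *After*; During period fits use only the last
three cycles to minimise entrainment transients.

## Synthetic oscillator population

Each simulated cell is a Poincaré (amplitude–phase) limit-cycle oscillator
integrated by Euler–Maruyama (default step 0.05 h):

    dx = [−ω_i y + λ x (A − r) + K (x̄ − x) + F_x] dt + σ dW
    dy = [ ω_i x + λ y (A − r) + K (ȳ − y) + F_y] dt + σ dW

with r = √(x²+y²), intrinsic frequency ω_i = 2π/τ_i where τ_i is drawn from
a normal distribution truncated to the circadian band [18, 30] h, radial
relaxation λ toward amplitude A, and all-to-all mean-field coupling K (the
stand-in for culture density: denser culture ⇒ larger K).

**Temperature drive.**  The normalised drive is z(t) = (temperature −
cycle midpoint)/ΔT, i.e. −½ in cold and +½ in warm *inside the cycling
window*, and exactly 0 under constant temperature, so Before/After segments
and the surroundings of a single pulse are genuinely unforced.  The default
forcing mode is the phase-sensitivity (infinitesimal-PRC) form: a pure
tangential kick of magnitude ε·z·sin(β − φ).  Two observations motivated
this over a fixed-direction vector force (which remains available as
`forcing_mode="vector"`): (i) fibroblast cold pulses show a biphasic
*phase* response but no systematic *amplitude* response, and a tangential
kick reproduces exactly that; (ii) a vector force drives large radial
excursions whose amplitude-modulation sidebands corrupt 3-cycle cosine fits
of the entrained waveform by several tenths of an hour.  The sensitivity
direction β = 1.1 rad places the integrated delay zone of a 10-h cold pulse
at roughly CT6–CT18 and the advance zone elsewhere, the empirically
observed arrangement.

**Observation model.**  b(t) = baseline₀·2^(−t/halflife)·(1 + (x+A)/(2A)) +
N(0, σ_obs), sampled every 0.5 h (the 30-min camera exposure).  The
exponential envelope emulates luciferin consumption / signal rundown.

**Defaults and why.**  τ mean 24 h, τ sd 1.5 h (free-running periods near
24 h with realistic cell-to-cell spread); λ = 0.1 /h (weakly stiff limit
cycle); ε = 0.6 (calibrated once so a T20 cycle entrains the whole
circadian band within three cycles; the single-pulse experiments use
ε = 0.3, which produces delay/advance group means of a few circadian
hours); K = 0 (fibroblast default; coupling is opt-in); phase noise
0.05 /√h and observation noise 2 gray levels, baseline 150 gray levels with
a 72-h half-life — chosen once to visually resemble published single-cell
traces: slow rundown, clearly rhythmic but visibly noisy.  The generator is
a phenomenological stand-in, not a mechanistic claim: it reproduces
entrainment, biphasic pulse responses and coupling-dependent
synchrony/amplitude, but not transcription–translation delays, spatial
signalling, or cell division.

**What passing tests do not show.**  Real recordings have non-Gaussian
camera noise, drift, focus changes, and cells whose intrinsic parameters
wander; results on synthetic data bound algorithmic correctness, not
biological performance.

## Movie rendering

Cells become isotropic Gaussian spots (σ = 1.5 px default) whose
*integrated* intensity equals the trace value per frame, on a constant
background with optional Gaussian noise, salt ("hot-pixel") artefacts, and
a reflected random walk for motility.  Ground-truth positions are returned
for tracker validation.

## Imaging chain

* **Kalman stack filter** — per-pixel scalar recursion with gain-derived
  measurement variance R = g·V₀/(1−g) and process noise q = (1−g)·V₀.
  These hold the posterior variance at V₀, so the Kalman gain is constant
  at 1−g: the filter is the steady-state exponential smoother (defaults
  g = 0.8, V₀ = 0.05); g = 0 passes the input through unchanged.  Because
  the smoother lags a 20–24-h oscillation by about 2 h, the pipeline tracks
  spots on the smoothed stack but measures intensities on the unsmoothed
  (outlier-cleaned) one.
* **Outlier removal** — per frame, pixels deviating from their
  (2r+1)² neighbourhood median (edges replicated) by strictly more than the
  threshold are replaced by that median; defaults r = 1, threshold 100.
  The operation is idempotent for sparse artefacts (isolated hot pixels);
  on dense pure-noise images neighbourhood medians shift after replacement
  and exact idempotence is not guaranteed.
* **Background** — mean of (four) cell-free rectangular ROI means per
  frame, subtracted from extracted traces.
* **Spot tracking** — global dynamic programming (Viterbi) over per-frame
  3×3 local maxima reachable within `max_step_px`; path score is the sum of
  stack-normalised intensities minus `motion_penalty`·Σ(squared
  displacement).  The global optimum lets the track ride out the dim trough
  of a bioluminescence cycle, where greedy trackers wander.  The default
  penalty (1.0 per px²) is tuned for sub-pixel-per-frame motility; fast
  spots need a smaller value.  An optional centre-of-mass step refines the
  integer path to sub-pixel precision.  Immobile cells (manual-ROI style)
  use a fixed-position track so one extraction path serves both modalities.
* **Extraction** — mean gray value in a (2r+1)² window (default 3×3)
  centred on the tracked position, clipped at frame borders.
* **Viability QC** — a cell is excluded when its final-24-h mean falls
  below 10% of its first-24-h mean ("strong reduction") or when no peak is
  detectable in the final 48 h ("loss of rhythmicity").  Both thresholds
  are operationalisations of qualitative criteria and are config-exposed.

## Preprocessing

Maximal gray values are normalised to 255; background is subtracted
(negatives allowed); trends are removed by subtracting a centred 24-h
running average (49 samples at 0.5 h), with the raw minimum added back to
preserve magnitude comparability.  Edge handling: the running window
truncates (shrinks) at the trace ends — the first and last half-window
(12 h) are flagged as edge-affected in trace metadata, and the pipeline's
cosine fits exclude them; including them biases 60-h period fits by about
−0.2 h.  The "minimal gray level" added back is the per-trace raw minimum
(whether the original convention was per-trace or per-experiment is
ambiguous; this choice is config-free but documented).

## Cosinor fitting

Model b(t) = a·cos(2π·t/τ − θ) + offset.  (A printed form with "2πτ·t"
appears in the literature; only division by τ makes τ a period in hours,
and that is what is implemented.)  Initialisation: largest periodogram peak
inside the 18–30-h band gives τ₀; projection on the cos/sin pair at that
frequency gives a₀ and θ₀; the segment mean gives offset₀.  A band peak
below twice the mean off-DC power flags the fit `low_power`.  Optimisation:
Levenberg–Marquardt, relative-RSS tolerance 1e-8, iteration cap 500;
parameters are canonicalised to a ≥ 0, θ ∈ [0, 2π) (whether amplitude
should be sign-constrained is unstated in the source convention; the
canonical form is equivalent).  Non-convergence flags the result rather
than raising; constant segments yield a = 0 with the mean as offset.
Standard errors come from the Gauss–Newton covariance at the optimum.  The
circadian filter accepts 18 ≤ τ ≤ 30 inclusive ("between 18 and 30" is
read inclusively).  Relative amplitude is a divided by the mean of the
*unprocessed* segment.

**During-fit windows.**  During fits use the last three cycles; the fit
additionally stops 4 h short of the release because the trend estimate of
those samples is increasingly dominated by post-release free run, which
otherwise biases the fitted During period by up to +0.16 h (measured on
noise-free simulated cells; the 4-h guard leaves ≲0.1 h across the
circadian band).

## Peaks, circadian time, responses

* **Peak picking** — candidates are local maxima of an 11-h running
  average, separated by at least 12 h (half a circadian cycle — a guard
  against noise-induced double peaks); around each candidate an ordinary
  least-squares parabola over exactly 30 samples (15 h) of the unsmoothed
  processed data gives the peak as its vertex; non-concave fits or vertices
  escaping the window are rejected with reasons.
* **Circadian time** — during cycles, one circadian day (24 CT h) is
  rescaled to the cycle length with CT12 at the end of the cold phase; in
  free run, real hours since a reference PER2::LUC peak are multiplied by
  24/τ and anchored at CT18.  The division convention (CT = hours·24/τ) is
  the default everywhere; the multiplicative variant (hours·τ/24) exists
  behind `ct_mode="multiplication"` because the two appear inconsistently
  in the source conventions, and division is the one under which a fixed
  real-hour shift counts for *fewer* circadian hours in longer-period
  cells.
* **Phase shifts** — the Before fit is extrapolated to the expected peak;
  the actual peak is the picked peak nearest the expected one (required
  within ±τ/2, otherwise the pairing is ambiguous and an error lists it);
  shift = (expected − actual)·24/τ, delays negative.  Stimulus onset CT is
  anchored at CT18 = last Before peak.  Stimulus onset (not offset or
  midpoint) is used as "the" circadian time of a 10-h pulse — an arbitrary
  but fixed convention.
* **PRC/ARC assembly** — shifts with onset in [CT6, CT18) form the delay
  group, the rest the advance group; group means ± SEM and a two-sample
  t-test carry the statistics.  A 4th-order polynomial fitted on CT
  unwrapped at CT6 is display-only.  Amplitude response is the ratio of
  relative amplitudes after/before the pulse.
* **Entrainment filter** — phase-relationship analyses admit only cells
  whose During period is within ±1 h (inclusive) of the cycle length.
* **Phase relationship** — per cell, the mean signed lag between the last
  two cold onsets and their nearest peaks, regressed (OLS) on the
  free-running period.

## Circular statistics

Formula-level implementations after Batschelet/Zar (the original analyses
used closed-source software; re-implementation makes numeric differences
explainable).  Mean direction and resultant length R̄ from the unit-vector
mean (mean undefined, flagged, when R̄ < 1e-12); Rayleigh Z = nR̄² with
p = exp(√(1+4n+4(n²−Zn)) − (1+2n)) (unreliable below n = 3, warned);
Watson–Williams F = g·(N−2)(R₁+R₂−R)/(N−R₁−R₂) with g = 1 + 3/(8κ̂), κ̂
from the pooled within-group resultant via Fisher's approximation, referred
to F(1, N−2); a pooled R̄ below 0.45 triggers a validity warning.  CT maps
to angle as 2π·CT/24 with CT0 at angle 0, counterclockwise.  Monte-Carlo
calibration (uniform null for Rayleigh at n = 17; equal-mean von Mises
κ = 2, n = 20 per group for Watson–Williams; 10⁴ replicates each) is part
of the acceptance suite.

## Pipeline, determinism, problem sizes

`TemperatureCycleExperiment.fit()` runs QC → preprocess → segment → cosinor
fits (+ circadian filter) → peaks → circadian phases → Rayleigh per stage →
first-stimulus shifts → PRC assembly → entrained-cell phase-relationship
regression, and returns tidy tables.  All randomness flows from a single
integer seed; outputs contain no timestamps, so identical config + seed
reproduce byte-identical files.

Demonstration problem sizes: the T20 demonstration uses 20 cells × 240 h;
the T24 demonstration uses 200 cells (its headline quantity is a
difference of two population period means, and the Before mean of an
n-cell draw from τ ~ N(24, 1.5) carries sampling error 1.5/√n h, so a
larger simulated sample keeps Monte-Carlo error well below the effect
scale); pulse-response experiments use 40 cells × 192 h with one 10-h cold
pulse each (random initial phases sample the whole circadian cycle of
onsets in one run).  Movie fixtures are 48×48 px × 241 frames.

## Known limitations

Single-component cosinor only (no damped or multi-component fits, no
wavelet/Hilbert instantaneous phase); all-to-all coupling (no spatial
structure); no stage-drift correction or cell segmentation in the imaging
chain; the 3-cycle cosine fit of an entrained, phase-modulated waveform has
an intrinsic window sensitivity of order ±0.1 h that no windowing choice
fully removes; Oriana's exact p-value conventions may differ from the
series approximations used here in the third decimal.
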