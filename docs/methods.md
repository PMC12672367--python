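# Methods

## The model

Falling asleep is treated as a critical transition of a dynamical system.
The brain's EEG is mapped, epoch by epoch, into a normalised feature space;
the Euclidean distance of the instantaneous feature vector from the
sleep-onset centroid is the *sleep distance* `s(t)` (units: s.d. of each
feature over the falling-asleep period).  `s(t)` stays on a plateau during
bedtime wakefulness and collapses abruptly in the last minutes before
sleep.  That trajectory is modelled by an overexploitation-type fold
(saddle-node) system

    dx/dt = r x (1 - x/K) - c x^2 / (x^2 + h^2),      c(t) = c0 + m t

where `x` is the sleep distance, `r` (1/min) a restoring rate opposing the
approach to sleep, `K` (s.d.) the carrying capacity — the maximal bedtime
sleep distance, `h` (s.d.) the half-saturation scale of the reduction
drive, and `c` the control parameter (sleep drive), ramping linearly at
rate `m` (1/min) from `c0 = 1` at the start of the fitted trace.  For
suitable parameters the system is bistable over an interval of `c`; the
upper end of that interval is a fold where the wake-like equilibrium
annihilates and the state drops to the sleep branch.  The control value
`c*` at the fold, mapped through the ramp to a clock time `t*`, is the
wake-sleep tipping point.  Note the distinction between the tipping point
(`c` crossing `c*`) and the visible collapse of `x(t)`: near a fold the
escape is slow ("slow passage"), so the trace falls a few minutes after
`t*`.

Equilibria at fixed `c` are `x = 0` plus the nonnegative real roots of the
cubic `r (1 - x/K)(x^2 + h^2) = c x`, solved by `numpy.roots`; stability
follows the sign of the state derivative of the right-hand side.  The
diagram scans `c` at step 1e-3 and refines the fold by bisection on the
positive-root count.  The "three-solution" bistable zone refers to the
three positive branches; `x = 0` is reported separately.

## Fitting

The fit maximises `R^2 - RMSE` between the integrated model and the
observed `s(t)` (RK45, relative tolerance 1e-6).  `R^2 = 1 - RSS/TSS` uses
an *uncentred* TSS (the sum of squared target values); a flag offers the
conventional centred definition.  The search:

1. `x0` = mean of the first 20 samples; `K` pinned to the mean of the
   first 100 samples, with `r` and `m` rescaled inversely to any `K`
   change (so the fold stays inside the window);
2. a `K` grid: +0.25 per step for 10 steps, keeping the `K` with the best
   `R^2`;
3. a sequential hill-climb on `r` (step 0.02), `m` (0.005) and `h`
   (0.001), capped at 250 iterations per parameter.

Two optimisation choices are this package's own.  First, the initial ramp
rate is data-driven: the fold of the initial parameter set (`r = 1`,
`h = K/10`, `c0 = 1`) is placed where the smoothed trace first drops
through `K/2` — the observed collapse — rather than at an arbitrary point;
this realises the requirement that the initial function bifurcate within
the trace's time range.  Second, because the sequential single pass is a
local search whose result depends strongly on that initial `m`, the search
is multi-started over five scalings of it (0.7–1.3) and the coordinate
sweep repeats up to twice while the objective improves; the best objective
wins.  On synthetic traces with known parameters this removes the local
optima that a single pass falls into, without changing any printed step
size or iteration cap.

A fit *fails* when the optimal parameters admit no bistable zone (no fold)
or the input is degenerate (constant); failures carry a reason and no
tipping point.  A tipping point after sleep onset is flagged invalid.

## Feature base

50 features per 6-s epoch (3-s hop), averaged across channels; the 47-set
omits sigma power, entropy rate and spectral slope:

- **Spectral (15)** — the epoch is band-passed 0.1–32 Hz, first-differenced
  (whitening, to suppress the 1/f background), and a multitaper PSD (4 DPSS
  tapers, NW = 2.5) is computed and aggregated onto a 1-Hz bin grid, then
  normalised to unit total power.  Band powers (delta 1–4, theta 4–8,
  alpha 8–12, beta 12–30 Hz) are means of normalised PSD bins, logged;
  five ratios (delta/alpha, theta/beta, theta/alpha, delta/theta,
  alpha/beta) are log quotients; peak band frequencies are argmax bins;
  the spectrum centroid is the power-weighted mean frequency; total power
  is the pre-normalisation whitened total, logged.  The exact ratio list
  is a registry convention (configurable).
- **PAC (6)** — for each ordered band pair (lower phase to higher
  amplitude), the whitened epoch is FIR band-pass filtered (zero phase,
  even order, three cycles of the band's low edge), Hilbert-transformed,
  and the modulation vector `z = A e^{i phi}` summed over complete phase
  cycles, normalised by the summed per-cycle mean amplitudes: a value in
  [0, 1].
- **Temporal coherence (4)** — the epoch is split into six 1-s segments;
  magnitude-squared coherence spectra over all 15 segment pairs are
  averaged and summed over each band's bins.
- **CATCH-22 (22)** — the canonical set, implemented from the published
  feature definitions on z-scored epochs; inner loops are numba-compiled
  and cross-checked against pure-Python references in the tests.  The
  registry exposes the field aliases "dwelling time"
  (`SB_BinaryStats_mean_longstretch1`) and "prediction error"
  (`FC_LocalSimple_mean3_stderr`).
- **Extras (3, 50-set only)** — sigma (12–16 Hz) power; LZ76 entropy rate
  `Lz log2(l) / l` of the epoch binarised about its median; the aperiodic
  exponent from a robust log-log linear fit of the raw multitaper PSD over
  0.1–32 Hz (one reweighting pass drops strong positive residuals, i.e.
  oscillatory peaks).

nfft = fs implies 1-Hz spectral bins; the multitaper periodogram is
evaluated at native epoch resolution and averaged into those bins rather
than truncating the tapered epoch to fs samples.

## Preprocessing

Cardiac artifacts: R-peaks from the ECG channel by Pan-Tompkins (5–15 Hz
band-pass, derivative, squaring, 150-ms integration, adaptive threshold,
200-ms refractory); per EEG channel the mean R-peak-centred 2-s segment is
subtracted at every beat, with each beat's subtraction clipped at the
midpoints to its neighbours so overlapping windows are not subtracted
twice.  Fewer than three beats: pass-through with a warning.

Bedtime: per channel, 30-s-epoch RMS above 2x the median flags an epoch;
the pass repeats twice with the median recomputed over unflagged epochs
(the repeat's median base is a package decision); flags are unioned across
channels; the first clean epoch is the new bedtime.  Artifact rejection of
6-s epochs (RMS > 2.5x channel median, union across channels) applies to
group-level analysis only; individual-level traces keep all epochs for
continuity.

## State space and group traces

Features are z-scored per recording (or with cohort-pooled statistics for
group analysis), referenced to the sleep-onset centroid (per-feature
median over the first 10 min after onset; onset = start of the first two
consecutive N2 epochs), and the distance is gap-corrected by subtracting
its minimum.  NaN features inside the norm are skipped with a
`sqrt(M / M_valid)` rescale so the distance scale is comparable across
epochs (a package decision).  Latencies outside [3, 90] min are flagged
excluded, as are onsets with mean sleep score below 1.5 over the first
10 min.  Group traces bootstrap 200 values per timestamp from
onset-aligned series, smooth with a 20-timestamp moving median, and t-test
each timestamp against the first-10-min baseline with Bonferroni
correction.

## Early-warning signals

Lag-1 autocorrelation and variance of linearly detrended residuals in a
trailing 100-sample (5-min) window.  The group-level trend is tested with
a linear mixed model (EWS ~ time, random intercept per subject); a
significantly positive time coefficient is the critical-slowing-down
signature.  A singular mixed fit falls back to a t-test of per-subject OLS
slopes, flagged in the output.

Two statistical caveats shape how the package exercises this machinery on
synthetic data.  First, consecutive rolling windows overlap by 99%, so
EWS values are strongly serially dependent and an i.i.d.-error model at
full resolution is badly anticonservative (stationary series reject far
above 5%); `trend_test` therefore takes a `stride`, and the package's
analyses subsample at one value per window length, which restores a
near-nominal false-positive rate.  Second, the window-based detrended
lag-1 autocorrelation saturates once the system's recovery time exceeds
the window, so slowing is only measurable when the relaxation rate is
comparable to the epoch hop; the EWS study conditions accordingly use a
fast-relaxation parameterisation of the fold model (r = 10/min, recovery
time of seconds, dynamic noise 1.0/sqrt(min)), under which the approach
to the fold raises the detrended autocorrelation from ~0.55 to ~0.88 and
the variance several-fold, while stationary controls stay flat.

## FPCA and the control parameter

Functional PCA is discretised: each group-level feature curve is
ridge-smoothed (Whittaker second-difference penalty, default 1e-3 — a
package default, the original strength being unspecified), weighted by
trapezoidal quadrature, and decomposed by ordinary PCA; components are
rendered as mean ± component, and per-feature scores are normalised to
[-1, 1] (positives by the max positive, negatives by |min negative|), with
representative features above |0.9|.  Features are ranked as
control-parameter proxies by |cosine similarity| / DTW distance against
the fitted ramp `c(t)`; DTW uses the classic symmetric unit-step dynamic
programme with absolute-difference local cost.

## Prediction

Training on one night stores the onset centroid, that night's
normalisation statistics, the gap, and the critical distance `x*` of its
fold fit (trace windowed to the last 30 min before onset, causally
median-filtered, window 20).  Multi-night training pools centroids by
median, normalisation over all training epochs, and `x*` by median over
successful fits.  Streaming: each incoming epoch is featurised, z-scored
with the *training* statistics, its distance to the trained centroid
computed (training gap subtracted, floored at 0) and causally
median-filtered — strictly causal by construction.  Tipping is predicted
at downward crossings of `x*` that stay below for at least 1 min; the
prediction is the last such crossing never followed by an upward re-cross,
earlier ones being erroneous-early; a prediction after sleep onset is
invalid.  Accuracy is the cosine similarity against the post-hoc `s(t)` of
the test night (referenced to the test night's own centroid and
statistics).

## Synthetic data: what it emulates and what it does not

`simulate_bifurcation_series` integrates the fold model with a linear
ramp; `noise_sd` adds i.i.d. Gaussian observation noise.  An optional
`process_noise_sd` (default 0) integrates Euler–Maruyama state noise
instead; this is required for critical slowing down to be observable,
since EWS reflect noise relaxing *through* the drift — observation noise
alone carries no autocorrelation signature.  EWS analyses therefore use
process noise (0.4 /sqrt(min)); fitting-recovery analyses use observation
noise (0.1 K), matching the additive-noise reading of the trace model.

`simulate_eeg_night` builds each channel as: a 1/f background whose
exponent steepens from about 1.0 (wake) to a subject-specific 1.5–2.1
(sleep); band-limited Gaussian components (delta/theta/alpha/beta) whose
RMS amplitudes follow the stage plan through 45-s raised-cosine ramps
(wake: alpha- and beta-dominant; N2: delta/theta-dominant); 0.75-s
spindle bursts at a subject-specific 12.5–15.5 Hz after the transition
(rate 6/min); and an optional cardiac template leaking 6 µV into every EEG
channel, with a ~1 mV ECG channel.  A per-subject seed fixes the sleep
spectral profile so sleep-onset centroids cluster by subject across
nights, while bedtime wake amplitudes vary freely per night; latencies are
drawn log-uniformly inside the [3, 90]-min inclusion window.

This generator reproduces the *spectral* phenomenology of falling asleep,
not its physiology: no neural-mass dynamics, no REM, no movement or ocular
artifacts, no gradual within-stage microstructure beyond the amplitude
ramps.  Passing tests therefore demonstrate that the analysis chain
recovers engineered transitions of the kind it assumes — not that real
EEG meets those assumptions.

## Problem sizes and test conditions

The package's study conditions are desk-scale by choice: recovery
analyses use 20 traces of 36 min (≈ 27 min before the fold, ≈ 9 min
after, mirroring the 30-min-pre/10-min-post analysis window) at noise
0.1 K; EWS analyses use 8 approach-to-fold paths and 50 four-subject
stationary null cohorts; the prediction cohort is 4 subjects x 4 nights
with 5–11-min latencies and 12 min of N2.  The acceptance script
regenerates all of these from its `--seed`.

## Known limitations

- Tipping-time identifiability degrades with the distance from trace
  start to the fold (errors scale like that distance times the relative
  error in `m`); very long plateaus yield correspondingly coarser tipping
  estimates at the printed step sizes.
- The CATCH-22 implementation follows the published definitions but is
  not bit-identical to the reference C library (histogram binning and
  Welch conventions differ in minor details); tests pin its behaviour
  with independent brute-force oracles instead.
- The EDF writer targets plain 16-bit EDF with 1-s records; EDF+
  annotations are not written.
- The fold model is not compared against alternative transition models;
  fit quality is reported, not model evidence.
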