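# Methods

This document specifies the signal model, the detector variants, the
evaluation and tuning machinery, the synthetic generator, and the numerical
choices behind `gazefix`. Package units: gaze positions in scene-camera
pixels, internal signals in px(/s), thresholds and reported quantities in
degrees of visual angle via a single isotropic scale `deg_per_px` (default
0.075 °/px, fixed by the correspondence 42 °/s = 560 px/s for the
reference scene camera).

## 1. Signal model

A recording is a strictly increasing timestamp vector `t` with gaze
positions `(x, y)` in scene-camera pixels, nominally 200 Hz.

**Smoothing.** Positions are smoothed with a Savitzky–Golay filter
(3rd-order polynomial, 55 ms window, `mode="interp"` so the edge windows
are handled by evaluating the boundary polynomial). Window lengths given in
milliseconds are converted to samples by `round(ms · rate / 1000)` forced
odd (centered windows need an odd sample count). The filter preserves
polynomial traces up to its order exactly.

**Velocity.** Forward differences
`v[i] = (p[i+1] − p[i]) / (t[i+1] − t[i])`; the final sample replicates its
predecessor so all series stay aligned sample-for-sample. Speed is the
Euclidean norm.

**Dispersion.** Over a centered window (default 25 ms),
`d = (max x − min x) + (max y − min y)`. At the recording edges the window
shrinks to the available samples; this is computed with max/min rank
filters in `mode="nearest"`, which is exactly equivalent to shrinking
because replicated edge values never change a max or min.

**Head-motion compensation.** Global optic flow `(u, v)` of the scene
camera approximates the image-content velocity induced by head motion.
The compensated (relative) velocity is `v_rel = v_gaze − v_content`.
The compensated dispersion is defined per window center as the dispersion
of the residual between the actual trajectory and an *ideal* trajectory
that carries the center gaze point along the integrated flow. Because
dispersion is translation-invariant, this equals the plain dispersion of
the flow-detrended trajectory `q(t) = p(t) − ∫ flow dt`, which is how it is
computed (one cumulative trapezoidal integral instead of a per-center
loop); the equivalence is asserted against the literal per-center
construction in the test suite.

## 2. Optic flow

**Estimator.** For each consecutive frame pair, an 11×11 grid of points
(inset 5 % from the borders) is tracked with pyramidal Lucas–Kanade. Two
numerical choices matter:

- an integer-pixel global translation is first estimated by FFT
  cross-correlation and used to initialize every point, so the iterative
  refinement always starts inside its convergence basin even for large
  inter-frame shifts;
- image windows are sampled with cubic B-splines on precomputed
  coefficient pyramids, avoiding the systematic bias of bilinear
  interpolation.

Points whose tracking window would leave the frame, or whose gradient
matrix is near-singular, are dropped; the global flow is the mean
displacement of the surviving points divided by the frame interval,
time-stamped at the frame-pair midtime. A pair with no surviving points
yields (0, 0) with a logged warning. On synthetic textured frames the
round-trip error is ≈ 10⁻³ px/s (requirement: 0.5 px/s).

**Resampling.** Flow is linearly interpolated onto the gaze timestamps;
outside the covered span the nearest endpoint is held.

**Head-motion intensity.** `o_RMS(t) = sqrt(RMS(u)² + RMS(v)²)` over a
centered window (default 205 ms), computed with cumulative sums and
shrinking edge windows.

## 3. Detector variants

All four variants label each sample **fixation** iff its signal is
*strictly below* the threshold, else **gap**:

| variant | signal | threshold |
|---|---|---|
| I-VT | speed (°/s) | fixed `v_thr` |
| I-DT | dispersion (°) | fixed `d_thr` |
| I-VAT | speed (°/s) | `T(t) = T0 + g · o_RMS(t)` |
| I-DAT | dispersion (°) | `T(t) = T0 + g · o_RMS(t) · w_d` |

Each variant can run on raw or compensated signals (`compensation=True`).
With zero flow, every adaptive/compensated variant reduces *exactly*
(label-for-label) to its plain counterpart.

For I-DAT the o_RMS speed (°/s) is scaled by the dispersion window length
`w_d` (seconds, default 0.025) so that the additive term has the units of a
length: it represents the extra dispersion a window accumulates when the
scene moves at o_RMS for its duration. Any residual scale mismatch is
absorbed by the tuned gain `g`.

Defaults (`T0 = 42 °/s`, `g = 0.70`, `w = 205 ms`, `a_thr = 1.7 °`,
`t_thr = 42 ms`, `d_min = 54 ms`) are mean optimal values for naturalistic
200 Hz head-mounted recordings and should be re-tuned per dataset.

## 4. Event post-processing

Sample runs are aggregated into events: an event starts at its first
sample's timestamp and ends at the first timestamp of the next run (the
last event ends at the final timestamp; a single-sample trailing run yields
a zero-extent event that is retained but excluded from metrics). Event
sequences must tile the recording with strictly alternating labels — this
invariant is validated after every operation.

Two filters are applied once each, in this order:

1. **Micro-saccade filter** — delete every *interior* gap whose amplitude
   (angular distance between the gaze positions at its first and last
   samples, from the smoothed trace) is `< a_thr` **or** whose duration is
   `< t_thr`, merging the flanking fixations. Edge gaps are never merged.
2. **Short-fixation filter** — relabel fixations shorter than `d_min` as
   gaps and coalesce.

The order matters: a brief fixation flanked by sub-threshold gaps survives
(the gaps are merged first) but would be deleted under the reversed order;
this witness is part of the test suite. Applying the pair twice equals
applying it once on all tested random and pipeline-generated sequences;
a pathological exception is conceivable (a relabeled short fixation can
coalesce with kept gaps into a low-amplitude gap that only a *third* pass
would remove) but has not been observed in practice.

Ground-truth annotation uses the stricter conjunctive rule: gaps with
amplitude < 2° **and** duration < 50 ms are merged into fixations.

## 5. Evaluation

**Event level.** Same-label events are matched one-to-one, greedily by
descending temporal IoU with a minimum criterion of 0.7 (ties: earlier
ground-truth onset, then earlier predicted onset). Unmatched predictions
are false positives, unmatched ground truths false negatives;
`F1 = 2TP / (2TP + FP + FN)`. Because disjoint events cannot both have
IoU ≥ 0.7 with the same counterpart, each event has at most one eligible
candidate and the greedy matching is provably optimal; this is also
verified against exhaustive assignment in the tests. The metric penalizes
fragmentation three-fold: one fixation split into two sub-criterion pieces
converts one TP into two FP plus one FN; the merged-fixation error is
symmetric (two FN plus one FP).

Timing differences (predicted − ground-truth onset/offset, ms), binned
metrics (by saccade amplitude, fixation duration, or peak flow speed), and
a 3×3 event confusion matrix are also provided.

**Sample level.** Cohen's kappa `κ = (p0 − pc)/(1 − pc)` with the chance
agreement from the product of marginals. Degenerate convention: if
`pc = 1`, κ is 1 when the sequences agree everywhere, else 0.

## 6. Coherent tuning

All six parameters (`threshold`, `gain`, `window_ms`, `a_thr`, `t_thr_ms`,
`d_min_ms`) are tuned jointly on an exhaustive Cartesian grid, maximizing
the mean per-recording fixation F1; ties resolve to the lexicographically
smallest parameter vector. Per-recording signals (smoothing,
differentiation, flow resampling, o_RMS per window length) are cached
across grid points, making full grids feasible. Recordings without
ground-truth fixations are skipped with a warning.

Cross-validation is k-fold over recordings, stratified by condition
(static/dynamic dealt round-robin after a seeded shuffle, so each fold's
condition ratio is within one recording of the global ratio). Each fold
reports validation F1 (overall and per condition), kappa, and its selected
parameters; their across-fold mean is the "average optimal parameter set".
Tuning curves pin one parameter and re-optimize all others per value.

## 7. Synthetic generator

The generator emulates the statistical structure of naturalistic
head-mounted recordings at 200 Hz:

- **Fixation durations** — log-normal (σ = 0.6). The location parameter is
  derived *analytically* so that the expected fixation-time fraction
  equals the configured target (default 0.83):
  `E[fix] = E[sacc] · tgt / (1 − tgt)`, with `E[sacc]` in closed form from
  the amplitude distribution.
- **Saccades** — amplitudes log-normal (median 5°, σ = 0.7); minimum-jerk
  position ramps whose peak speed is `1.875 · A / D`; durations follow
  from the main-sequence power law `peak = k · A^b` (k = 70, b = 0.6).
  Saccade directions recenter gaze when it strays beyond a quarter of the
  frame from the center. Saccades qualifying as micro-saccades
  (amplitude < 2° and duration < 50 ms) are pre-merged into ground-truth
  fixations, matching the annotation rule.
- **VOR episodes** — with probability 0.25 a fixation hosts an episode
  whose flow speed follows a sin² bell up to the configured peak
  (default 300 °/s, capped at the physiological 800 °/s); the gaze point
  rides the *left-Riemann* integral of the flow, so the forward-difference
  gaze velocity reproduces the flow sample-for-sample exactly.
- **Noise** — additive white Gaussian position noise (sd 1.5 px).
- **Flow output** — the ground-truth flow field downsampled to a 30 Hz
  camera time base (frame midtimes).
- **Frames** — optionally, periodic random textures translated by the
  trapezoid-integrated flow using exact Fourier shifts, for validating the
  flow estimator; inter-frame shifts above 15 px are rejected as
  untrackable.

Identical configurations and seeds give bit-identical outputs.

**Scope.** The generator is a *test instrument*, not a behavioral model:
fixational drift and tremor are absent (fixation anchors are static unless
a smooth-pursuit fraction is configured), saccade curvature and
post-saccadic oscillations are not modeled, VOR gain is exactly 1, the
flow field is spatially uniform, and noise is white rather than
tracker-correlated. Measured descriptive statistics (fixation-time
fraction ≈ 0.84, main-sequence exponent ≈ 0.59 at b = 0.6) land within the
acceptance tolerances by construction, not by fitting.

## 8. Numerical choices

- Forward differences with last-sample replication keep every series the
  length of the recording; detection thresholds then see the saccade at
  its onset sample.
- The left-Riemann integral in the generator is chosen so that the
  *forward-difference* velocity of the integral returns the integrand
  exactly; the analysis-side detrending uses trapezoidal integration,
  which is second-order accurate for arbitrary flows.
- Window operators (dispersion, o_RMS) shrink at the edges rather than
  padding, so no sample inherits fabricated data.
- Peak saccade speeds in `descriptive_stats` are measured after a short
  (25 ms) Savitzky–Golay smoothing — long enough to suppress differentiated
  noise, shorter than the briefest physiological saccade so peaks are not
  attenuated. With the default 55 ms window the measured main-sequence
  exponent would be biased upward (small-saccade peaks are attenuated
  more); with no smoothing it is biased downward by noise inflation of
  small-saccade peaks.
- CSV floats are serialized with `%.9g`, so write/read round trips
  preserve values to float precision for all realistic magnitudes.

## 9. Limitations

- The flow estimator assumes a single global translation per frame pair;
  rotation about the optical axis, zoom/parallax, and independently moving
  objects violate the model (the grid-mean is robust to *sparse* outliers
  only).
- Smooth pursuit is not a separate class: pursuit at speeds above the
  threshold is labeled gap, below it fixation.
- Blinks and tracking dropouts are not modeled; input timestamps must be
  strictly increasing and positions finite.
- Event matching at IoU 0.7 is insensitive to boundary errors below 30 %
  of event duration; timing statistics complement it.
- Kappa is computed on the two-class sample labeling; it is sensitive to
  class imbalance (a fixation-heavy recording can have high agreement but
  moderate kappa).
- `postprocess` applies each filter exactly once; see §4 for the
  (unobserved) pathological non-idempotence corner case.
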