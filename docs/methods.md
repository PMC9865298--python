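# Methods

## Problem and pipeline

posturekit classifies four static human postures — standing, sitting,
bending, lying — from a single chest-worn tri-axial accelerometer. A static
sensor reads the gravity vector (magnitude 1 g), so posture is encoded in
the *direction* of the measured acceleration relative to the wearer's
standing orientation; movement and sensor noise ride on top of it.

The stages run in deployment order:

1. **Unit conversion.** Raw sensor units map to g through the per-axis
   affine model `value_g = (raw − offset)/sensitivity` (default sensitivity
   660 raw units per g), then saturate at the ±2 g full scale. Saturation is
   a clip, not a rejection, mirroring the physical sensor; clipped-sample
   counts are logged.
2. **Noise filtering.** Order-8 Butterworth low-pass at 10 Hz. Batch
   processing applies it forward-backward (`zero_phase_batch`): no group
   delay, and the *magnitude* response is squared (effective order 16),
   which is documented behaviour, not an accident. `causal_stream` applies a
   single causal pass, matching what a real-time deployment experiences.
   The digital design uses the bilinear transform; at 50–100 Hz sampling its
   stopband attenuation is *stronger* than the analog closed form
   `|H(f)| = (1+(f/f_c)^{2n})^{−1/2}` because of frequency warping. Tests of
   the closed form therefore run at a sampling rate high enough (1 kHz) for
   warping to be negligible.
3. **Calibration.** A ≥ 2 s static standing recording must show (a) both
   non-gravity axes within `tolerance_g` of 0 g, (b) the gravity axis within
   `tolerance_g` of ±1 g, (c) per-axis std ≤ `static_std_max_g`. Defaults
   are 0.15 g and 0.05 g; the tolerance is application-configurable because
   no canonical value exists. The passing mean vector, normalized, becomes
   the tilt reference, so per-subject mounting offsets cancel in every
   subsequent tilt computation. Calibration runs on filtered data
   (noise-robust; the alternative — raw — would only widen the measured
   std). Chest tilt is `α = arccos(v̂ · r̂)`; magnitudes below 0.1 g raise a
   signal-loss error rather than returning a meaningless angle.
4. **Windowing and features.** 350 ms windows advanced by 50 ms. At 50 Hz
   these are non-integer sample counts (17.5/2.5), resolved by a ceiling
   rule (18/3) so every window covers at least the nominal duration; at
   25 Hz the same rule gives 9/2. Thirteen time-domain feature families are
   computed per axis (full layout, 39 columns). Two definitions deviate
   deliberately from the naive forms because signed accelerations make
   `a·ln(a)` and `log₂(a)` undefined: the entropy features operate on window
   energy — `WENT = −Σ pᵢ ln pᵢ` with `pᵢ = aᵢ²/Σa²`, and
   `LEE = Σ log₂(aᵢ² + 1e−12)`. Standard deviation is defined as √variance
   (population, 1/N). Skewness/kurtosis are the standardized moments
   `m₃/σ³`, `m₄/σ⁴`, returned as 0 when σ < 1e−12 (constant windows). The
   static acceleration change (SAC) is the window range of a separate
   gravity-tracking low-pass — order 2, cutoff 0.5 Hz by default, gentle
   enough to follow posture changes while rejecting movement; the dynamic
   acceleration change (DAC) is the range of the main filtered signal.
5. **Feature selection.** An L1-penalized multinomial logistic regression on
   standardized columns; a family's weight is the max |coefficient| over
   classes and axes, and zero-weight families are pruned. The pipeline's
   default *selected* layout hard-codes the six families that survive in
   practice — MAV, VAR, SKEW, KURT, DAC, SAC (18 columns) — with
   `lasso_select` provided to reproduce and inspect the procedure. Whether
   selection should act per column or per family is genuinely open; family
   level was chosen because a family is the unit a practitioner would
   enable or disable.
6. **Classification.** Random forest (gini, depth 30, 25 trees), decision
   tree (gini, depth 19), and KNN (k = 13, Minkowski p = 2 — the standard
   Euclidean choice — distance weights). KNN consumes features standardized
   with training-fold statistics, because distance metrics need comparable
   scales; tree models consume raw features, which are split-invariant.

## Evaluation protocol

Per-class counts are one-vs-rest TP/TN/FP/FN, giving per-class accuracy
`(TP+TN)/total`, precision `TP/(TP+FP)`, recall `TP/(TP+FN)` and
`F1 = 2TP/(2TP+FP+FN)`; overall accuracy is trace/total and
precision/recall/F1 are macro-averaged (each class weighted equally —
appropriate for a 4-class problem reported as single numbers). 0/0 ratios
report 0 with a warning.

Cross-validation builds 10 stratified folds. Repetition *i* tests on fold
*i*, reserves fold *i+1* as a validation set (an 80/10/10 split; the
validation fold is held available for model selection and never scored),
and trains on the remaining eight. Mean ± std over the ten test folds is
reported. When group ids are present, whole groups stay within one fold.
**The default group is the contiguous recording segment** (one posture
bout): consecutive windows overlap by 15 of 18 samples, so splitting a
segment across train and test would leak nearly-identical rows. Grouping by
whole subject would be stricter still, but seven subjects cannot populate
ten disjoint folds; segment grouping removes the overlap-leakage mechanism
while keeping the ten-fold protocol intact. This choice materially affects
absolute accuracies and is configurable (`groups=None` for plain stratified
folds).

The 25 Hz experiment decimates by an integer factor *after* the 10 Hz
low-pass (which already acts as the anti-alias filter for the 12.5 Hz
Nyquist), then re-windows with the ceiling rule.

## Synthetic cohort

No public recordings exist for this task at the required sensor placement,
so the package ships a generator whose defaults define the study
conditions used by every test and by `scripts/acceptance.py`:

- Gravity direction tilts about the device x-axis by a posture angle θ:
  standing 0° ± 4°, sitting 20° ± 5°, bending 60° ± 8°, lying 90° ± 6°.
  Sitting deliberately sits closer to standing than to bending — with one
  chest sensor those are the confusable pairs.
- Each (subject, posture) draws **one** characteristic angle from its
  distribution and holds it for every bout: people sit the way they sit.
  Within-bout variation comes from breathing (0.005 g at 0.25 Hz along the
  chest normal) and white sensor noise (0.02 g per axis), filtered and
  clipped like real data.
- Each subject wears the device with a small mounting rotation
  (N(0, 3°) about x and y, bounded below 15°), cancelled downstream by the
  calibration reference.
- Posture changes cosine-interpolate θ over 1 s; transition samples carry
  the target posture's label (configurable by shortening `transition_s`).
- The default cohort is 7 subjects × 3 cycles × 4 postures × 30 s at
  50 Hz — ≈ 42,000 windows — sized so the full three-model evaluation runs
  in minutes on one CPU.

What the generator does **not** emulate: posture-dependent movement
dynamics (real standing sways more than lying, making variance-type
features informative), gait or falls, gyroscope channels, electrode-style
drift, and age-related tremor. Consequences are discussed below.

## What passing tests do and do not show

The simulation validates the *pipeline* — that filtering, calibration,
windowing, the feature algebra, fold construction and the classifiers are
implemented correctly and that tilt information flows end to end — not
field performance on real elderly wearers. Absolute accuracies on synthetic
data (RF ≈ 0.99, DT ≈ 0.99 under grouped 10-fold CV) say the classes are
separable under the stated geometry; real-world accuracy depends on
behaviours the generator does not model.

One consequence is a known, measured limitation: because the generator
gives every posture the same dynamic-noise level, only the MAV family
carries orientation signal among the six selected families, and KNN's
standardized Euclidean distance is diluted by the remaining noise-driven
dimensions. Grouped-CV KNN accuracy is ≈ 0.86 on the default cohort
(≈ 0.98 if restricted to MAV columns), predominantly standing/sitting
confusion, while the per-column-splitting tree models are unaffected. On
real data, posture-correlated dynamics would make those dimensions
informative and lift KNN; the simulation cannot show that.

## Numerical choices and degenerate inputs

- Window label = majority of per-sample labels; ties break toward the label
  occurring earliest in the window.
- `WENT` of an all-zero window is 0 (no energy distribution exists);
  constant non-zero windows give ln N.
- Decimation requires an exact integer rate ratio; anything else is a
  configuration error, not a silent resample.
- Grid search enumerates candidates in grid insertion order and keeps the
  first maximizer on ties.
- Benchmark latencies time the per-window path (single-window feature
  computation + single-row prediction); filtering is excluded because a
  streaming deployment filters incrementally as samples arrive, not per
  window. `real_time_ok` compares the mean latency against the sampling
  period 1/fs (20 ms at 50 Hz). CPU/RAM percentages are process-level
  best-effort probes and are never compared across machines.

## Known limitations

- Single-axis tilt kinematics: full 3-D posture (twist, lateral lean) is
  out of scope, matching what one chest accelerometer can observe.
- The Lasso selector subsamples very large matrices (seeded) for
  tractability; selection on the full matrix is available via
  `max_rows=None`.
- KNN underperforms on the synthetic cohort for the structural reason
  above; its synthetic-data accuracy should not be read as a prediction of
  its real-data ranking.
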