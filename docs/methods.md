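# Methods

This note documents what `graspid` computes, the assumptions behind the
synthetic study generator, the numerical choices, and the limits of what
the test suite can establish.

## The measurement model

A grasp trial is a prehension movement with three phases: **reach**
(movement onset to object contact), **grasp** (contact to release; the
object is transported during this phase), and **release** (release to
return to rest). Two synchronized streams describe it:

* 20 reflective markers at 120 Hz (mm): three per finger along the
  phalange chain (thumb: metacarpal, proximal, distal), three on the
  metacarpals spanning the palm, two on the wrist.
* 5 fingertip force-sensor voltages at 960 Hz — exactly 8× the kinematic
  rate, so integer decimation aligns the streams.

### Joint angles

Let **c** be the centroid of the three palm markers and **n** the unit
normal of their plane (sign fixed by marker labelling order). For each
finger with marker chain (m₁, m₂, m₃):

* θ₁ = ∠(**n**, m₁ − **c**) ∈ [0°, 180°] — elevation of the finger base
  relative to the palm plane;
* θ₂ = ∠(m₂ − m₁, m₃ − m₂) ∈ [0°, 180°] — phalange flexion.

**Convention:** θ₂ is the angle between successive *direction vectors*, so
a straight finger reads 0° and flexion increases the angle. The source
analysis does not fix this convention; ours makes 0 = neutral, and all
tests are written against it. Both angles are invariant to rigid motion
and uniform scaling (verified to < 10⁻⁶ deg), which is why hand size per
se cannot explain subject separability. Left hands are mirrored in x
before processing so one convention serves all subjects.

Trajectories are low-pass filtered before angle computation: 4th-order
Butterworth, 15 Hz cutoff, applied forward-backward (zero-phase) so phase
boundaries are not shifted. Trials with missing marker frames are rejected
with an error naming the marker and frame range.

### Forces

Each subject calibrates each finger by pressing a spring-loaded platform
(k = 0.45 N/mm) to the rail end three times; the optically tracked
displacement gives F = kΔx per sample. The three repetitions are
interpolated onto a common voltage grid spanning the overlap of their
ranges, averaged, monotonized by isotonic regression, and anchored so the
baseline voltage maps to 0 N. The resulting curve is piecewise linear;
out-of-range voltages clamp to the endpoints with a logged warning
(sensor drift should degrade, not crash). Averaging is done in force space
on a voltage grid — whether the original analysis averaged in force or
voltage space is unstated; this is our documented choice.

Raw voltages are band-stop filtered (4th-order Butterworth, 48–52 Hz,
zero-phase) to remove mains hum, then decimated 8:1 with a polyphase FIR
(line-extension padding, so a constant baseline has no edge droop).

### Features

Phase segmentation is not specified by the source analysis; ours uses a
wrist-speed threshold (50 mm/s, sustained ≥ 6 frames) for movement
onset/end and a total-fingertip-force threshold (0.5 N) for
contact/release, each followed by a backtrack to a noise floor. The floors
adapt to the rest-phase noise actually observed (1.1 × its 99th
percentile) because rectified sensor noise has a positive mean after
calibration; after reaching the floor the backtrack continues down any
remaining monotone slope. On synthetic trials at default noise the
detected bounds sit within ±5 frames of the generator's ground truth.

Each trial becomes a 15 × 500 matrix (per finger: θ₁, θ₂, F), resampled by
linear interpolation on a normalized time axis (the 15 Hz pre-filtering
makes higher-order interpolation immaterial). Three croppings:

* `full` — whole movement → 500 samples;
* `no_release` — release discarded, remainder → 500;
* `phase_equalized` — reach → 250, grasp → 250, concatenated (removes the
  between-subject variance in the reach/grasp duration proportion).

In the latter two modes non-contact force samples are replaced with
N(0, 1) draws from a seeded stream, since they contain only sensor noise.
Angle entries and force entries are z-normalized separately, each with one
(mean, std) pair pooled over all trials; normalization happens after time
normalization, on the final 500-sample matrices. Flattening is row-major
in the fixed feature order (7500 values; 5000 for the angles-only view,
which is an exact row subset).

### Classification

t-SNE embeds the flattened vectors into 3-D (perplexity 10–15 for
per-object subject clustering; 50 for grip-type clustering over the three
geometrically distinct objects). A weighted kNN votes with wᵢ = dᵢ⁻²
(k = 10), distance floored at 10⁻¹² so duplicates dominate as the limit
dictates; vote ties break to the lexicographically smallest label, and
equidistant neighbours resolve by training order (stable sort). Stratified
5-fold cross-validation scores the pipeline; `mean_accuracy` is defined as
the pooled trace accuracy of the summed confusion matrix (identical to the
fold mean for equal fold sizes). Classes with one trial cannot be
stratified and stay in training with a warning.

**Embedding leakage.** The faithful pipeline embeds *all* trials before
splitting folds, so test points shape the embedding. This is deliberate —
it reproduces the original "t-SNE, kNN, cross-validation" chain — and
optimistic as a generalization estimate. `GraspPatternModel(...,
holdout="feature_space")` provides the leakage-free alternative: the same
weighted-kNN CV run directly on the z-normalized feature vectors (t-SNE
has no out-of-sample transform here, so a train-only embedding cannot
place test points).

**t-SNE learning rate.** scikit-learn's `auto` learning rate floors at 50,
which overshoots on datasets of a few dozen well-separated trials and
shatters clusters. We use n/12 (the early-exaggeration heuristic) floored
at 10; with it, four 10σ-separated Gaussian clusters embed with silhouette
0.90, and cross-validated accuracy saturates where the feature-space
classifier saturates.

### Sensitivity analysis

All subsets of sizes 2–14 of the 15 features (32,751) are scanned: the
excluded rows are replaced per trial by fresh N(0, 1) noise — matching the
z-normalized data's distribution, so pipeline parameters stay unchanged —
and the embedding + kNN + CV chain is re-run. Because the embedding is
stochastic, each subset is evaluated `n_repeats` times (default 3) with
fresh noise and averaged; per-object tables are averaged unweighted into a
cross-object table. Each (subset, repeat) derives its seed from a stable
hash of (master seed, subset, repeat), so results are reproducible and
independent of evaluation order. From the table: per-size max/mean/min
profiles, best-k subsets (ties → first in deterministic order), and a
time-window variant that keeps one 50-sample window and noises the rest
(10 non-overlapping windows per 500-sample trial; stride configurable).

A full 32,751-subset scan at study scale is an hours-long batch job; the
test suite and acceptance experiments exercise reduced grids (≤ 8
features), which preserve every structural property of the scan.

## The synthetic study generator

The generator emulates the study design: 31 subjects × 5 objects × 7
trials (35 grasps/subject, 1085 trials), five objects named for their
roles (tennis ball, full/half bottle, soft/stiff ellipsoid; the two
bottles share one geometry, as do the ellipsoids).

* **Templates.** Angle templates are low-order harmonic expansions
  (4 harmonics) on normalized movement time: a fixed population mean
  (θ₁ dips, θ₂ rises toward mid-movement) plus per-subject and per-object
  perturbations. Perturbation coefficients are scaled so the *pointwise*
  std across draws equals the configured effect scale exactly
  (cos² + sin² = 1 per harmonic pair) — effect sizes are directly
  interpretable in degrees. Force templates are half-sine bumps (zero at
  contact and release, ≥ 0) with per-subject peaks and shape
  perturbations; objects scale forces via a weight/stiffness factor.
* **Forward kinematics.** Planar-per-finger chain constructed so the two
  angles fully determine marker geometry: m₁ = c + L₁(cos θ₁ n + sin θ₁ u),
  m₂ = m₁ + L₂ d₁, m₃ = m₂ + L₃(cos θ₂ d₁ + sin θ₂ w), segment lengths
  scaled by hand size. Extraction inverts this exactly; the noise-free
  round trip errs < 0.05° (resampling and filtering only). A random rigid
  rotation + translation is applied per trial. Richer hand models would
  add nothing the analysis consumes.
* **Subject-specific timing.** Preferred phase durations are part of the
  subject signature: each subject's mean durations deviate from the
  population mean in proportion to the subject effect scale (so zero
  effect ⇒ identical timing), and per-trial jitter scales with the trial
  noise level (so zero trial noise ⇒ exactly repeated trials). Without
  this coupling, timing differences leak subject identity even at zero
  nominal effect and classification cannot be driven to chance.
* **Sensors.** Per-subject mildly nonlinear response V = aF + bF²
  (a ∈ [0.35, 0.55] V/N, b ∈ [0, 0.01] V/N²), white sensor noise
  (0.02 V), and a pure 50 Hz mains sinusoid with random phase — matching
  the band-stop filter's target. The calibration session simulates the
  spring-platform presses through the same sensor model.
* **Defaults.** subject effect 1 (deg / N pointwise), trial noise 0.25,
  object effect 1, marker noise 0.1 mm (the motion-capture system's
  accuracy). The real study does not characterize its inter-subject
  effect distribution, so these are free parameters chosen to produce the
  qualitative structure it reports — dense per-subject clusters with
  accuracy in the mid-90s at study-like sizes — not estimates of it.
* **Determinism.** Every profile, trial, object effect and calibration
  draws from its own `SeedSequence` stream keyed by (seed, role, indices);
  identical configs reproduce datasets bit-for-bit regardless of call
  order.
* **Planted-feature datasets.** `generate_feature_dataset` bypasses the
  kinematic layer and emits z-normalized feature matrices directly, with
  chosen rows informative and the rest pure noise. The `independent`
  structure gives each informative row its own subject template; the
  `coded` structure binary-codes subject identity across the informative
  rows (row j carries ± effect × curve_j by bit j of the subject index),
  making the planted set *jointly necessary and sufficient*: dropping any
  planted row merges subject pairs and visibly caps accuracy. The coded
  design is what the recovery experiments use, because with additive
  independent signals the marginal value of one feature can sit inside
  embedding noise and "best subset" degenerates into tie-breaking.

### What the generator does not emulate

Marker occlusion/dropout and soft-tissue artefacts; sensor hysteresis,
temperature drift and shear forces; anatomical abduction/adduction DoF;
object slippage vibrations; session-to-session changes in a subject's
pattern. Passing tests therefore show that the *pipeline* recovers the
structure it assumes when that structure is present — they cannot show
that real grasping data contains such structure, nor reproduce the
original study's exact accuracy values, which depend on its unreleased
recordings.

## Evaluation experiments (`graspid.evaluation`)

* **Parameter recovery** runs the full chain (generation → extraction →
  embedding → kNN → CV) on 10 subjects × 2 objects × 5 trials: accuracy
  ≥ 0.95 when the subject effect is 10× the trial noise, within ±0.05 of
  the 0.10 chance at zero effect, and non-decreasing over a fixed-seed
  effect sweep (0, 0.3, 1, 3). Each object is scored as the mean over 3
  embedding seeds — the same repeat-averaging the sensitivity scan uses —
  because single t-SNE runs at n = 50 have several percent run-to-run
  spread.
* **Planted recovery** scans all size-3 subsets of 8 features on coded
  datasets (8 subjects × 7 trials, effect 2, noise 0.4, 150 samples) over
  10 seeds; the planted set must rank first in ≥ 80% of runs, and the
  full-grid max-quality curve must plateau at sizes ≥ 3 and drop steeply
  below. This is the scaled-down analogue of the full 6-of-15 scan, sized
  for an exhaustive enumeration that runs in minutes.
* **Round-trip fidelity and filter responses** are computed on noise-free
  trials and long test tones (band-stop measured in steady state, 2 s edge
  trim, since the narrow zero-phase notch rings for about a second).

`scripts/acceptance.py` reports all of these from scratch under one seed.

## Known limitations

* The faithful pipeline's accuracy is optimistic (embedding leakage, see
  above); use `holdout="feature_space"` for honest generalization.
* Sub-percent calibration bias remains near the voltage-grid edges
  (isotonic boundary + baseline anchoring); negligible against grasp-force
  scales.
* `segment_phases` assumes trials begin and end at rest; recordings that
  start mid-movement will mis-detect onset.
* The full sensitivity scan is embarrassingly parallel but implemented
  serially; at 31 subjects × 5 objects it is an overnight job.
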