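# Methods

This note documents the measurement model behind `mouthkit`, the defaults
it ships with, what the synthetic simulator does and does not emulate, and
the design decisions that were ours to make.

## 1. Measurement model

### Input

A session is a sequence of frames, each carrying 2D landmarks in the
standard 68-point facial convention (0-based). The pipeline uses:

- indices **39** and **42** — inner canthi (left and right inner eye
  corners), for calibration and roll alignment;
- indices **48–67** — the 20-point mouth contour, for the ellipse fit.

Custom index maps are supported (`LandmarkFrame.index_map`); the mouth
contour needs at least five non-degenerate points for a conic fit.

### Roll alignment

Before any fitting, each frame is rotated about the midpoint of the two
inner canthi so the inter-canthal line is horizontal. This step is what
makes the reported opening invariant to in-plane head roll: the "vertical
extent" of a rotated ellipse is not rotation-invariant on its own, so the
vertical direction must be defined in a face-fixed frame, not the camera
frame. It also makes the fitted inclination angle face-relative, which is
what the symmetry grade needs.

### Ellipse fit

The mouth contour is fitted with a general conic constrained to be an
ellipse using the numerically stable direct least-squares formulation of
Halir and Flusser (1998). Points are first normalized (centroid shift and
isotropic scaling) for conditioning; collinear or coincident inputs are
rejected with a clear error. The constrained fit returns an ellipse by
construction, so no post-hoc discriminant check can fail on valid input.
The fit quality reported is the root-mean-square Sampson (gradient-weighted
algebraic) residual in pixels, a first-order approximation to orthogonal
distance. On noise-free boundary samples the fit recovers center, axes and
inclination to well below 1e-6 (verified against dense boundary sampling
and an independent geometric least-squares fit in the test suite).

### Opening and symmetry

For canonical parameters — semi-axes `a ≥ b > 0`, inclination
`Φ ∈ (−90°, 90°]` — the opening is the exact vertical extent

    E = 2 sqrt(a² sin²Φ + b² cos²Φ)   (pixels, face-aligned frame)

and the symmetry angle is

    θ = atan2(b sinΦ, a cosΦ)   (degrees)

θ is the rotation that levels the major axis; |θ| ≤ |Φ| whenever `b ≤ a`,
and θ → Φ as the ellipse approaches a circle. Grading uses |θ|.

### Calibration

Pixel measurements are converted to physical units by fixing the
inter-inner-canthus distance at **3.5 cm** (a stable adult facial
dimension): `scale = 3.5 / d_eye_px` cm/px, and
`opening_mm = E · scale · 10`. The measurement is therefore invariant to
uniform rescaling of the frame (camera distance under orthographic
viewing). Individual deviation from 3.5 cm enters the result
multiplicatively; the reference is configurable (`eye_distance_reference_cm`).

### Session aggregation

The exercise protocol asks the patient to hold each maximal opening for
about **3 s**. Per session, the pipeline:

1. finds the longest contiguous plateau of frames at ≥ **95 %** of the
   session's maximum per-frame opening;
2. takes the middle **1 s** window of that plateau;
3. samples **5 evenly spaced time points** in the window (nearest frame;
   duplicate frames at low fps trigger a warning);
4. reports the mean of those 5 openings as the session's maximum opening.

If the plateau is shorter than the window, all plateau frames are used and
a warning is attached. Aggregation is frame-rate invariant for clean
signals (verified at 30 vs 60 fps).

### Grading

Half-open intervals, closed on the left:

- opening: F1 < 15 mm, F2 [15, 25), F3 [25, 35), F4 ≥ 35 mm; openings
  above 50 mm are flagged as outside the expected physiological range;
- symmetry: F4 < 5°, F3 [5, 10), F2 [10, 15), F1 ≥ 15°.

The boundary convention (15.0 mm is F2, not F1) is an explicit design
decision, tested exhaustively on a 0.001-unit grid.

## 2. Detector training losses

For training landmark/box detectors feeding this pipeline:

- **focal loss** −α_t (1−p_t)^γ log p_t, natural log, probabilities
  clamped at 1e-12, batch reduction by mean; defaults α_t = 0.25, γ = 2;
- **GIoU** = IoU − (|C| − |union|)/|C| with C the axis-aligned enclosing
  box; the loss is 1 − GIoU ∈ [0, 2];
- **keypoint MSE** = mean squared Euclidean landmark error;
- **joint loss** = λ₁·focal + λ₂·(1−GIoU) + λ₃·MSE, returned with a
  per-component breakdown (defaults λ = 1, 1, 1).

## 3. Evaluation metrics

Micro accuracy, per-class recall, macro-F1 (classes with zero denominator
contribute F1 = 0 with a warning), MAE, normalized mean error
(error / interocular distance), failure rate (default NME threshold 0.08),
cumulative error distribution and precision–recall curves (one point per
distinct score threshold, descending), Bland–Altman limits of agreement
(mean difference ± 1.96 · SD, sample SD with ddof = 1), and relative
degradation `100 · (baseline − perturbed) / baseline`.

## 4. Cohort splitting

Splits operate on whole patients so no patient's segments straddle a
partition boundary:

- **70/15/15 stratified split**: each patient is assigned a stratum (modal
  grade of their samples, seeded tie-break); within a stratum, patients are
  placed largest-first into the partition with the largest remaining
  deficit, with a seeded shuffle breaking size ties. Realized fractions
  land within one patient of target per stratum; single-patient strata
  produce a warning.
- **k-fold**: scikit-learn's `StratifiedGroupKFold` (patient id as group,
  grade as label, seeded shuffle).
- **subset selection**: seeded sampling of `round(fraction × N)` records
  without replacement, with an optional external denominator (e.g. "20 %
  of the full dataset" drawn from a held-out challenge pool).
- **SMOTE-style oversampling**: synthetic minority samples interpolated on
  segments between a class member and one of its k = 5 nearest same-class
  neighbors (Euclidean distance on z-scored features, interpolation in the
  original space). Synthetic records are flagged and inherit the parent's
  patient id; singleton classes are duplicated with a warning. Intended
  for training partitions only.

## 5. Synthetic exercise simulator

The simulator exists to give the measurement pipeline exact, analytically
known ground truth. It emulates:

- a rigid 68-point 3D face template (dimensions in cm; inner canthi 3.5 cm
  apart; mouth 6 cm wide by default) whose 20 mouth points lie exactly on
  an ellipse;
- an open–hold–release exercise profile (rest 2 mm, 1.5 s ramp, 3 s hold,
  1.5 s release, 30 fps);
- rigid head pose as Rz(roll)·Ry(yaw)·Rx(pitch), orthographic projection
  at a default 20 px/cm, and isotropic Gaussian landmark jitter.

The configured peak opening is the **true vertical extent**: the ellipse's
semi-minor axis is solved from the requested extent, width and inclination,
so truth labels are exact by construction (this bounds feasible
inclinations for small openings; cohort defaults keep |Φ| ≤ 3°).

It does **not** emulate: perspective distortion, lens distortion,
illumination or occlusion effects (landmark jitter is the only noise
proxy), non-rigid facial soft tissue, detector-specific error structure,
or temporal tracking artifacts. Conclusions about real detectors must come
from real data; the simulator validates the geometry and bookkeeping.

Under this model the pose biases are analytic and are used as oracles:
yaw ψ inflates the recovered opening by `1/cos ψ − 1` (≈ 3.53 % at 15°,
because foreshortening shrinks the interocular calibration length while
the vertical mouth extent is unchanged), pitch shrinks it by `cos(pitch)`,
and roll leaves it unchanged thanks to the alignment step.

Cohorts are generated by largest-remainder apportionment of a grade mix
over patients, with per-grade peak-opening intervals
F1 (5, 15), F2 (15, 25), F3 (25, 35), F4 (35, 50) mm, optionally shrunk by
a boundary margin when studying noise robustness away from grade
boundaries. Per-session seeds are drawn below 2³¹ for portability.

## 6. Numerical and I/O choices

- Landmark CSVs are written with `%.17g` floats and read with pandas'
  `round_trip` parser, so write→read is bit-exact.
- Reports are JSON with sorted keys, 6-significant-digit floats, and an
  audit envelope (tool version, 16-hex-char SHA-256 config hash, input
  digest, and the input's own time range instead of wall-clock time), so
  identical inputs produce byte-identical files.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds stay below 2³¹.

## 7. Limitations

- The interocular reference (3.5 cm) is a population constant; individual
  anatomy introduces a proportional scale error unless measured.
- Orthographic projection is assumed; at short camera distances perspective
  effects bias the calibration.
- Out-of-plane pose is measured as-is, not corrected; yaw/pitch biases are
  characterized (Section 5) but compensation is out of scope.
- The symmetry angle is an ellipse-inclination proxy for facial asymmetry,
  not a landmark-by-landmark asymmetry analysis.
- Grading thresholds are fixed clinical conventions, configurable but not
  learned from data.
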