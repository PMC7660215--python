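# Methods

This note documents the models, conventions and numerical choices behind
`tugkin`, and what its validation does and does not establish.

## Pipeline model

### Coordinate conventions

All sign conventions are centralized so alternatives are one-line
changes.

* **World frame** (simulator): right-handed, gravity 9.81 m/s² along −Z,
  X anterior at trial start. Accelerometers at rest sense the gravity
  direction (down); calibration negates it to obtain "up".
* **Anatomical triads** are right-handed with SI × ML = AP. SI points
  superiorly, AP anteriorly; ML completes the triad. Upright standing
  has SI = +Z, AP = +X for every segment.
* **Quaternions** are Hamilton, scalar-first (w, x, y, z); `q` rotates
  sensor-frame vectors into the provider's global frame. This choice
  must be fixed for the conjugation q p q⁻¹ to be computable. For purely
  sagittal motion the frame-one alignment absorbs a uniformly misread
  convention (a tested property); once heading rotations (turns) occur
  the two readings genuinely differ, which is why the convention is
  documented rather than auto-detected.
* **Angle signs**: flexion positive for hip and knee, dorsiflexion
  positive for ankle; a positive angle means the distal segment pitches
  anteriorly relative to the proximal one. Angles are zero at the
  upright frame-one reference — the parallel-axes construction implies
  this, so the pipeline reports change-from-standing rather than
  absolute anatomical angles.

### Two-pose calibration

`build_calibration_frame` follows the cross-product construction (SI
from standing gravity, ML from the standing × seated pair, AP = SI × ML,
ML re-derived for exact orthogonality). Two deliberate choices:

* **Seated tilt direction.** The seated pose pitches leg segments
  anteriorly but the trunk posteriorly, which flips the sign of the
  SI × v_sit cross product. Each roster placement therefore carries a
  `seated_tilt` attribute ("forward" for thigh/shank/foot, "backward"
  for the two trunk sensors) used to orient ML so that AP comes out
  anterior for every sensor and flexion angles are positive downstream.
* **Degeneracy guard.** The cross product is rejected when the two
  gravity directions are within 5° (configurable): below that the ML
  direction is numerically meaningless. Averaging windows: all provided
  frames for each pose (the standing pose is represented by the static
  hold at the start of the trial capture).

### Frame-one alignment and what it can(not) correct

Per-sensor frame-one DCMs map every sensor's upright axes onto the
canonical basis. A consequence worth stating explicitly, because it
shapes the whole error model: **any constant sensor-vs-segment mounting
rotation cancels exactly** for sagittal motion — the calibration axes,
the stream and the frame-one reference all carry the same constant
rotation, and zeroing at frame one removes it. Constant mounting error
therefore produces no bias. What does produce bias is a violation of the
frame-one parallel-axes assumption: an orientation change between the
static standing reference and dynamic movement (soft-tissue deformation,
strap migration, postural offsets). The synthetic generator models
exactly this distinction (below).

### Joint angles

Eq-level choice: the flexion angle is computed with the two-argument
arctangent of the projected SI components, `atan2(C_AP, C_SI)`, rather
than the arctangent of their ratio. The ratio form is undefined at ±90°
and sign-ambiguous beyond; sit-to-stand knee flexion exceeds 90° in
every trial, so this matters in practice, and a dedicated test sweeps
(−170°, 170°). Reference angles project the distal AP axis into the
proximal sagittal plane (projected-axis definitions in the style of
optical lower-body models); frames with a degenerate projection (distal
axis within 1e−6 of the plane normal) inherit the previous frame's
value. Reference angles are computed from ground-truth segment triads
supplied by the simulator; marker-level reconstruction and joint-centre
regression are out of scope.

### Error metrics

Bias = mean(IMU − reference), RMSE = root-mean-square of the same
difference, per trial × segment × joint × pair; |bias| ≤ RMSE is
asserted on every record. The reference channel (100/120 Hz) is linearly
interpolated onto the IMU timebase (40/60 Hz) — linear interpolation on
angle channels is adequate because inter-frame steps are a few degrees
at most; the interpolation error bound (2πfΔt)²/8 is tested. Segment
slices are half-open [start, end) so adjacent segments never share a
frame. Records with fewer than two frames in a slice are skipped.

### GEE comparison

One GEE per joint × segment × metric, cell-means design (one coefficient
per sensor pair = its least-squares mean), Gaussian working variance,
identity link, exchangeable working correlation clustered by
participant, robust sandwich covariance. The solver iterates GLS updates
with moment re-estimation of the dispersion (scale = Σr²/(N−p)) and of
the common correlation (ρ = Σ pairwise residual products / (scale ×
(total pairs − p))); these are the standard moment estimators, and the
implementation is verified in tests against both a dense-matrix
brute-force solve and an established GEE routine (agreement to machine
precision). Convergence: max coefficient change < 1e−8, cap 100
iterations, non-convergence flagged. Inference is Wald with the normal
reference and no multiplicity adjustment, matching how such tables are
conventionally reported; p > 0.05 cells are "highlighted" (unbiased, or
indistinguishable from the lowest RMSE). Ties for the lowest RMSE are
broken by deterministic pair order and logged.

**Small-sample caveat.** Sandwich-based Wald tests are asymptotic in the
number of clusters. Empirically (this package's own simulations) the
bias-vs-zero test rejects true nulls at roughly 10% with 7 clusters and
approaches the nominal 5% only above ~100 clusters; the type-I
calibration check therefore runs at 200 clusters × 3 observations with
intra-cluster correlation 0.3, where the measured size is 4–5%. P-values
from 7-subject studies should be read with this anti-conservatism in
mind; no small-sample correction is applied, by design.

## Synthetic-data generator

The generator emulates the measurement process the analysis assumes,
with analytic ground truth.

### Trajectories

Per-joint angles are piecewise C¹ curves: a quintic-smoothstep baseline
between posture keyframes per phase plus sin²(πcu) gait oscillations
(non-negative, attain their amplitude exactly, zero slope at phase
boundaries for integer cycle counts). Defaults: seated posture 80° hip /
85° knee / 5° ankle; sit-to-stand 1.5 s; walk passes 2.5 s with two gait
cycles (hip 30°, knee 60°, ankle 15°); turns 2 s with gentler
oscillations; stand-to-sit 1.5 s — a ~14 s TUG, realistic for healthy
adults on a standard chair. Because capture starts upright (the
orientation reference), a 0.5 s standing hold, a 2 s stand-to-sit
preamble and a 0.5 s settle precede the first annotated event. Segment
pitches chain down the kinematic chain (pelvis pitches at 0.15 × hip
flexion); both turns rotate all segments 180° about the vertical, which
exercises the full 3-D quaternion path without altering relative joint
angles. Phase durations get ±10% per-trial uniform jitter by default.
Event annotations are the exact phase boundaries, enabling round-trip
segmentation tests.

### Sensor and error model

A sensor stream is the true segment rotation composed with (in order,
segment side first): per-frame jitter, the movement-engaged offset, and
a constant static mount rotation:

* **Movement-engaged offset** (`offset_deg` about a chosen anatomical
  axis): ramps in smoothly during the preamble and persists — the
  mounting deforms between the static reference posture and dynamic
  movement, so frame-one alignment cannot remove it. A +d° ML offset
  appears downstream as exactly +d° bias when the sensor is the distal
  member of a pair (−d° when proximal). Per-subject realizations are
  drawn around the location's typical value
  (`offset_subject_sd_deg`), constant across a subject's trials — this
  is the source of within-subject correlation the GEE models.
* **Static offset** (`static_deg`): a constant sensor-vs-segment
  rotation present in both calibration poses and the whole trial; the
  pipeline cancels it exactly, and a test asserts it does.
* **Jitter** (`jitter_sd_deg`): independent small random rotations per
  frame, rotation-vector components i.i.d. N(0, σ²); zero during the
  static standing hold. The sagittal component passes straight into the
  angle error, so pipeline RMSE converges to σ (a tested recovery).
* **Accelerometer noise** (`accel_noise_sd`, default 0.05 m/s²) on
  calibration frames; **reference noise** (default 0.5° additive white)
  on the reference channel — the optical system is a gold standard, not
  noiseless; both are set to zero in exactness tests.

Default per-location values (a few degrees of offset, 1–2.5° jitter,
larger over soft tissue such as the posterior thigh and shoe-mounted
heel, smaller over bone) are chosen once as a realistic operating point;
they are configurable placeholders, not estimates of any particular
cohort.

### Rates and sampling

IMU streams default to 60 Hz and the reference to 120 Hz (the study
hardware used 40/60 Hz and 100/120 Hz); both are sampled from the same
continuous functions at their own rates. The defaults are nested
(60 | 120), so linear interpolation of the reference onto the IMU
timebase is exact at IMU timestamps and the noise-free round trip
recovers ground truth to < 1e−6° (in practice ~1e−14). With non-nested
rate pairs (e.g. 100 vs 60 Hz) an O((Δt)²) interpolation floor of order
1e−3° appears; that is a property of resampling, not of the estimator.

### What the generator does not emulate

Raw gyroscope integration and sensor-fusion drift, magnetic
disturbances, marker-level optical noise and joint-centre regression
error, translational kinematics, non-sagittal joint motion (segments
move in the sagittal plane plus a shared heading rotation), and
time-varying soft-tissue artifact correlated with muscle activation.
Passing tests therefore demonstrate that the analysis chain is correct
and well-calibrated under its stated error model — not that any
particular hardware achieves these error levels in vivo.

## Determinism

All randomness flows from a single seed: subject-level generators (one
per subject, for mounting realizations) and trial-level generators (one
per trial, for duration jitter, sensor jitter and noise) are spawned
from independent seed-sequence children, so studies are byte-identical
across runs and insensitive to which subset of sensors is generated.

## Known limitations

* Bias reflects only reference-vs-frame-one discrepancies by
  construction; mechanisms that re-zero during a trial (strap slip
  mid-walk) are not modeled.
* The parallel-axes assumption is applied to all segments including the
  pelvis and foot, not only thigh/shank; all joints need a common frame
  and the same construction is used uniformly.
* GEE fits are per joint × segment cell (matching per-segment sample
  accounting) rather than one pooled model with interactions.
* Wald inference at 7 clusters is anti-conservative (see above).
* Angles are reported relative to the standing posture; absolute
  anatomical angles would require joint-centre/marker information that
  is out of scope.
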