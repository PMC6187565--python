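# Methods

This note records the models, conventions, parameter choices and known
limitations behind `imugait`, in the order the data flow through the
pipeline.

## Frames and conventions

Global frame: x forward, y left, z up; gravity `(0, 0, −9.81)` m/s², so a
resting accelerometer reads `+9.81` along its up axis.  Quaternions are
Hamilton-convention, scalar-first, and map the *sensor* frame to the
*global* frame (`v_g = R(q) v_s`); the predicted sensor-frame direction of
a global reference is therefore the conjugate rotation.  Euler angles are
intrinsic z-y-x (yaw, pitch, roll), pitch clamped to ±90° via a protected
arcsine.  Segment inclinations are sagittal, forward-lean positive, so a
segment inclined by θ reads static specific force `(g sinθ, 0, g cosθ)`
and its inclination rate is the negative mediolateral (y) gyro component.
Knee flexion is positive; ankle dorsiflexion positive, plantarflexion
negative.  None of these conventions is forced by physics; they are fixed
here once and used consistently by the simulator, the estimators and the
tests.

## Accelerometer and magnetometer calibration

**Model.** Small triad misalignment enters as
`a_meas = E a_true + b + n`, `E ≈ [[1,0,α],[β,1,γ],[0,0,1]]` with angles
below ~0.1 rad, `b` an additive bias, `n` white noise.  Static samples at
many orientations then lie on the ellipsoid
`(x−b)ᵀ E⁻ᵀE⁻¹ (x−b) = g²`.

**Fit.** With the quadric written as
`ax²+by²+cz²+2fyz+2gxz+2hxy+2px+2qy+2rz+d = 0`, least squares under the
quadratic constraint `4B − A² = 1` (A, B the first two symmetric
invariants) reduces, because the constraint touches only the six
second-order coefficients, to a 6×6 generalized eigenproblem by Schur
complement.  One subtlety: the constraint's quadratic form is positive
only for axis ratios below √3, so a genuine but elongated ellipsoid
appears in the spectrum on the infeasible side with a (near-)zero
eigenvalue.  Candidates are therefore screened by positive-definiteness
of the quadratic form (the defining ellipsoid property), ranked by
normalised algebraic residual, and the unit-constraint scaling is applied
whenever feasible — which it always is in the near-spherical sensor
regime.  Geometry (centre, semi-axes, axes) comes from the stationary
point and the eigendecomposition of the quadratic form; the axis-labelling
ambiguity is resolved by the closest-to-identity assignment, valid because
misalignments are small.

**Angles.** Identifying the fitted form with the model gives
`(g²Q)⁻¹ = EEᵀ`; normalising by its (3,3) entry (which equals one in the
model, removing any gravity-scale error) yields the closed-form
extraction `α = P₀₂`, `γ = P₁₂`, `β = P₀₁ − αγ`.

**Magnetometer.** The same fit on a figure-eight sweep gives the
hard-iron offset (centre) and soft-iron correction: the *symmetric*
positive-definite square root of the quadratic form, scaled to the
geometric-mean radius.  Choosing the symmetric root pins the rotational
ambiguity of the factorisation; a rotational soft-iron component is
absorbed into a constant heading offset, which the heading-reference
anchoring below neutralises.

**Protocol sizes.** Defaults: 64 orientations × 300 samples (a 3 s dwell
per orientation at 100 Hz) for the accelerometer; 12 000 samples (~2 min)
for the figure-eight sweep.  These follow from an error budget: a
misalignment-angle error Δ leaks the ±30 m/s² swing accelerations across
axes, displacing each stride by ≈ Δ·(stride length); keeping that below
the sensor-noise floor of the position chain needs Δ ≲ 2·10⁻⁴ rad, and
the fit error scales as noise/√N.

## Stance detection

Two per-sample criteria, fused at decision level:
`V = (a_x² + a_y² + a_z²)/g²`, thresholded through its trailing moving
variance (window N = 15 samples, λ₁ = 0.02) — near-constant on the
ground, strongly fluctuating in swing — and the trailing angular-rate
energy `E = Σ‖ω‖²/(σ_ω² W)` (W = 15, λ₂ = 1.5).  σ_ω² defaults to the
*second moment* of the rate over the first second (assumed quiet
standing), which normalises the energy to ≈ 1 at rest; a per-axis
variance would put the three-axis rest level near 3 and break the λ₂
threshold.  Thresholds were tuned on the simulator and are exposed in the
configuration.

Causal (trailing) windows erode the leading edge of every stance interval
by up to one window length — a deterministic group delay, since any
sample whose window overlaps swing fails the variance test.  The detector
compensates by advancing each onset by `max(N, W) − 1` samples
(configurable).  A morphological closing then fills holes shorter than
the minimum stance duration (a single noise spike poisons every window it
sits in, splitting an interval), and runs shorter than `min_stance`
(0.1 s) are discarded.  On simulated gait this yields frame agreement
above 95 % and event timing within a few samples.

Stance intervals longer than 2 s are classified as standing rest, not
gait stance: they still anchor zero-velocity updates but do not form
strides.  This cleanly separates the standing lead-in/out of a recording
from the gait cycles without any heuristic stride filtering.

## Attitude fusion

A Mahony-style PI complementary filter.  Per sample: error vectors from
gravity and (optionally) the magnetic field, PI feedback
`ω' = ω + k_p e + k_i ∫e dt`, quaternion propagation by a first-order
step with renormalisation.  Implementation decisions that matter:

- **Midpoint rates.** Propagation uses the mean of adjacent gyro samples.
  A left-endpoint rule leaves a half-sample attitude lag (≈ θ̇·Δt/2, up
  to ~1° at walking rates) that rectifies against the large swing
  accelerations into a deterministic vertical position drift of several
  millimetres per stride.
- **Confirmed quiescence gating.** The gravity correction runs only when
  the specific-force norm is within 5 % of g *and* the rate norm is below
  0.15 rad/s *and* both conditions hold over a centred 9-sample window.
  Movement onset/offset always leaves one or two samples whose specific
  force is gravity-like in norm but already points off vertical; without
  the confirmation window those samples inject a systematic per-stride
  tilt kick proportional to k_p.  Processing is offline, so the
  non-causal look-ahead is free.
- **Heading-only magnetic correction with unit gain.** The raw cross
  product on a dipped field couples heading error into tilt at roughly
  the vertical field fraction (~0.88 here) — harmless while gravity
  aiding runs, disastrous during swing when it is gated.  The error is
  therefore projected onto the predicted vertical axis and rescaled by
  the squared horizontal field fraction so one radian of heading error
  produces one unit of correction regardless of dip.
- **Anchored heading reference.** Absolute declination is unobservable to
  a wearable system, so heading is defined relative to the field observed
  during the initial standing stretch.  The pipeline averages the
  magnetometer over *all* stance samples (the foot revisits the standing
  orientation every stance), which both averages noise √N-fold and makes
  the stance-phase heading immune to residual calibration error at that
  orientation.  Without a reference the filter falls back to rebuilding
  one from each measurement by horizontal projection.
- **Gains.** k_p = 2.0, k_i = 0.2 by default (time constants of 0.5 s and
  10 s), chosen on the simulator as the best worst-seed position error
  with comfortable margin; 1.0/0.1 also works.  The integral accumulator
  is clamped at 0.02 rad/s (anti-windup): large enough to absorb any
  plausible residual gyro bias, small enough that wind-up from the
  initial convergence transient decays quickly.
- **Gyro bias** is removed in two passes: the mean rate over the initial
  standing second, then — for foot sensors — the mean over all detected
  stance samples, where the foot is truly stationary.

## Position and gait parameters

Specific force is rotated to the global frame, gravity subtracted, and
trapezoid-integrated twice.  Velocity is clamped to zero inside each
stance interval, eroded by 3 samples per side so a detection boundary off
by a sample or two never clamps genuine slow edge motion; the residual
velocity at each stance onset is removed by a linear ramp over the swing,
which cancels constant per-swing acceleration errors exactly.  The
trailing segment after the last update keeps raw increments (no terminal
anchor).

Strides are anchored at stance-interval starts (initial contact); length
is the horizontal displacement between median stance positions (medians
resist integration ringing), clearance the swing vertical maximum above
the mean level of the bounding stances, stride frequency counts two steps
per stride.  Cycle = stance + swing by construction.

Joint angles integrate the mediolateral rate difference between adjacent
segments, anchored by accelerometer-derived static inclinations.  Drift
is removed per stride: the knee is pinned to its standing value at stance
midpoints (the knee returns there in every stance); the ankle does not
return to a known value mid-stance, so its drift *rate* is estimated
instead by a Theil–Sen line through the values at phase-equivalent stance
midpoints — the median of pairwise slopes ignores midpoints that fall on
non-steady cycles (gait start/stop transients, terminal standing) — and
subtracted.

## Bilateral symmetry statistics

Knee-ROM symmetry uses a one-way ANOVA over stride pairs: the k-th left
stride and k-th right stride form group k, giving k groups of two and an
F statistic on (k−1, k) degrees of freedom.  Standard frequentist
semantics apply: small p is evidence against the null of equal group
means.  Cohort summaries report mean ± sample (n−1) SD.

## The simulator

The generator realises the configured stride length, clearance, cycle,
stance fraction and knee profile *exactly*: stance keeps the foot planted;
swing advances it along a 7th-order smoothstep with a sin⁴ clearance
bump.  Both primitives have vanishing end derivatives through the second
(advance) or first (clearance) order, so the *sampled* accelerations are
consistent with the positions under trapezoidal re-integration — with a
C⁰ or C¹ profile, sampling at 100 Hz alone introduces a deterministic
per-stride velocity bias of the order of millimetres per second, which
would be an artefact of the fixture rather than of the method under
test.  Thigh angles sweep sinusoidally with a smooth start/stop envelope;
the knee bump (sin², peaking mid-swing) is imposed directly and the shank
follows as thigh minus knee, so knee ROM is exact by construction.  Feet
run half a cycle out of phase.  Thigh/shank sensors translate with the
hip (mean of the feet) while rotating with their segment — a
sensor-on-the-rotation-axis approximation.

The sensor-error model applies, per segment: the non-orthogonality matrix
(defaults 0.5°, 0.3°, 0.8°), per-axis biases (accelerometer ±0.02 m/s²,
gyroscope ±0.01 rad/s, drawn deterministically per segment and seed),
white noise (0.02 m/s², 0.0175 rad/s ≈ 1°/s, 0.2 field units against a
45.7-unit field), and hard iron (10, −5, 3) plus diagonal soft iron
(1.1, 0.9, 1.0) on the magnetometer.  The global field is (22, 0, −40)
(arbitrary units, ~61° dip).  All randomness flows from one integer seed;
outputs are bit-reproducible.

**What the simulator does not model** — and what passing tests therefore
do not demonstrate about real recordings: soft-tissue artefact and strap
wobble, foot-ground impact transients and sensor saturation, gyroscope
scale-factor error and g-sensitivity, temperature drift, magnetic
disturbance from the environment (only constant sensor-fixed iron),
timestamp jitter or dropped packets, and non-sagittal (3-D) joint
kinematics.  Real-world accuracy will be worse than the simulator
figures; the simulator's role is to verify that the *algorithms* are
correct and that their error budget behaves as designed.

## Evaluating position accuracy

The headline check scores the estimated foot trajectory of simulated 60 s
walking sessions against ground truth.  Before scoring, the estimate is
registered to the truth frame with a single rotation about the vertical
plus a translation.  This is the minimal registration any comparison
against an external reference system performs: gravity fixes the shared
vertical, but the azimuth of an inertial-magnetic frame (set by the local
field, to ~0.05° given magnetometer-calibration residuals) and its origin
are arbitrary relative to the reference system's.  Over a 50 m walk an
0.05° azimuth offset alone is worth ~4 cm of cross-track displacement —
a frame convention, not a dead-reckoning error.  Both registered and
unregistered figures are returned by `imugait.evaluate`.

Problem sizes used by the validation suite and the reproduction script:
ten sessions of 43 strides (≈ 60 s at 100 Hz, ~6 000 samples each),
calibration protocols at their defaults.  Worst-seed registered RMS 3-D
position error is typically 4–8 mm against a 15 mm design bound.

## Known limitations

- Flexion axes are assumed aligned with the sensor y axis after mounting;
  no functional axis calibration.
- The stance detector's σ_ω² self-estimate presumes the recording starts
  with ≥1 s of quiet standing; so do attitude initialisation and gyro
  debiasing.
- Heading accuracy is bounded by magnetometer calibration (~0.05°
  azimuth); position error over long straight walks is cross-track
  dominated if no registration to an external frame is available.
- The ANOVA treats stride pairs as independent groups; no repeated-
  measures structure across visits.
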