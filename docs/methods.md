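# Methods

This note documents the models, conventions and numerical choices behind
`trunklab`, and what the synthetic-data experiments do and do not establish.

## Orientation estimation

Attitude is a scalar-first unit quaternion q = (q₁, q₂, q₃, q₄) for the
Earth-to-sensor rotation. The filter is the standard gradient-descent
complementary scheme for IMU/MARG fusion: per sample,

    q̇ = ½ q ⊗ (0, ω)  −  β ∇f / ‖∇f‖ ,    q ← normalize(q + q̇ Δt),

where ω is the gyroscope reading (rad/s) and f is the misalignment between
the sensor-frame prediction of the gravity direction (and, when the
magnetometer is enabled, the Earth field direction) and the normalized
measurements. The magnetic reference is re-derived from the current estimate
and flattened to the XZ plane each step, so field disturbances perturb only
heading, never roll/pitch — the trunk angle is therefore magnetometer-proof.

Conventions and parameters:

* Earth frame Z-up; a level, resting accelerometer reads +g on body Z.
  Gravity constant 9.80665 m/s².
* Euler angles are aerospace Z-Y-X (yaw about Z, pitch about Y, roll
  about X). The roll component is the trunk angle for all tests. Some
  published presentations of the quaternion-to-Euler map label the axes
  differently and one widely circulated form of the pitch equation is
  internally inconsistent (a term reduces to q₁q₃ − q₄q₁ so both products
  share q₁); we use the standard algebra and verify it by rotation-matrix
  round trips rather than transcribing any printed variant.
* Gimbal lock: the arcsin argument for pitch is clamped to [−1, 1]; no
  error is raised. Round trips are exact to 1e-6° for |pitch| ≤ 89°.
* Filter gain β = 0.1 by default (dimensionless correction authority,
  ≈ 5.7°/s of static convergence rate at unit-normalized gradient). The
  value is a conventional compromise between convergence speed and noise
  transmission; it is configurable and none of the timing results are
  sensitive to it because holds are quasi-static.
* Δt comes from consecutive timestamps, falling back to 1/51.2 s (the
  nominal wearable sampling rate) for the first sample or a broken clock.
* A zero-norm or non-finite accelerometer sample skips the correction for
  that step (gyro integration still runs); the stream length is preserved.
* `trunk_angle_stream` initializes the state from the accelerometer tilt of
  the first sample, which removes most of the static convergence transient;
  an explicit initial state can be supplied instead.
* Roll is reported signed. The session layer uses the absolute (wrap-aware)
  deviation from the reference, so the sign convention cannot change test
  outcomes.

## Test state machine

The examiner's start action is an input timestamp, not an auto-detected
posture: the reference angle is the stream angle at the nearest sample at or
before the start event. Termination is evaluated per sample with strict
inequalities — deviation *more than* 10° (Sorensen and side bridges) or 30°
(trunk curl), elapsed time *more than* 240 s, or a manual stop — with reason
priority manual > angle > time when simultaneous. The detected duration is
the first terminating sample time minus the start time, so it is accurate to
one sample period (1/51.2 ≈ 19.5 ms) against the underlying crossing time.

Design choices that were genuinely open:

* The 240 s cap is applied per attempt. A two-attempt Sorensen total can
  therefore exceed 240 s; the category lookup clips the total at 240 s (the
  top of the normative scale) in that case.
* The Sorensen second attempt is an optional second start event; the rule
  that a second chance follows an angle-drop finalization is advisory and
  not enforced by the machine.
* Angle deviation is computed wrap-aware across the ±180° seam as a defensive
  measure, although trunk angles stay far from the seam in practice.
* Timing uses stream timestamps exclusively, never wall clock, so offline
  reruns are byte-identical.

## EMG fatigue metrics

RMS, ARV and MVC are computed per epoch (default 1 s — short enough to
resolve fatigue trends at 51.2 Hz, long enough that the RMS estimate has
~10% sampling error) and over the whole test, since clinicians read a single
summary triple per session as well as the trend. Non-overlapping epochs are
used; a trailing partial epoch is kept only when at least half full, so no
row is dominated by a handful of samples. MVC is the maximum of the
*rectified* signal by default: the classical definition as a raw maximum
would ignore a strongly negative-going burst, which is physiologically
indistinguishable from a positive one; the raw maximum remains available via
a flag. No band-pass filtering or detrending is applied (the metrics are
defined on the recorded trace); an optional mean-subtraction toggle exists,
default off.

## Normative scoring

Category bins use the published integer edges (Sorensen 61/62 and 131/132;
side bridge 60/61 and 108/109; trunk curl 131/132) and cover the continuum
by assigning a duration to the bin with the largest lower edge not exceeding
it. The trunk-curl scale has only two labels; its printed edges overlap, and
the adopted bins (bad [0, 131], good [132, 240]) resolve the overlap in
favor of the good-bin lower edge. Bins and reference ratios are packaged in
`data/norms.yaml` and can be overridden per clinic.

The side-imbalance flag reads "side-to-side difference greater than 0.05" as
|right/left − 0.96| > 0.05, i.e. deviation from the published norm ratio;
deviation from exact symmetry (1.0) is available via `reference="unity"`.

## Reliability statistics

The one-way random-effects model treats each subject's pair of durations as
k = 2 interchangeable measurements: x_ij = μ + b_i + ε_ij with
b_i ~ N(0, σ_b²), ε_ij ~ N(0, σ_w²). From the ANOVA mean squares MS_B
(between subjects, n−1 df) and MS_W (within, n(k−1) df):

    ICC(1,1) = (MS_B − MS_W) / (MS_B + (k−1) MS_W)
    ICC(1,k) = (MS_B − MS_W) / MS_B

The *average-measures* form ICC(1,k) is the default: it is the form under
which the bundled validation dataset reproduces its published reliability
table (verified against an independent hand ANOVA and against pingouin's
ICC1k), and it answers the operative question — the reliability of the mean
of the two methods' readings. The single-measures form is available by flag.

Confidence intervals are the exact F construction: with F₀ = MS_B/MS_W,
F_L = F₀/F(1−α/2; n−1, n(k−1)) and F_U = F₀·F(1−α/2; n(k−1), n−1), the
average-measures bounds are 1 − 1/F_L and 1 − 1/F_U. When MS_W = 0 the
interval degenerates to (1, 1). Bootstrap intervals are out of scope.

Cronbach's α uses the two methods as items with n−1 variances:
α = 2(1 − (s_a² + s_b²)/s_{a+b}²). Bland–Altman differences are oriented
traditional − sensor (configurable); limits are x̄ ± 1.96 s with the n−1
standard deviation.

Display values are rounded half-up to 2 decimals; full precision is kept in
`*_exact` columns. Statistical packages that display three decimals and
tables that re-round those to two can differ from one-stage 2-dp rounding by
one unit in the last place when the exact value sits within 5e-4 of a
boundary (e.g. 0.5848 → 0.585 → 0.59); the acceptance tests compare at the
printed precision accordingly.

## Synthetic data

The generators emulate the study conditions: a subject holding a posture and
then failing it, recorded at 51.2 Hz.

* **Trajectory**: roll holds at `initial_roll` with Gaussian tremor
  (default 0.3° SD in the CLI — the amplitude of postural sway visible in
  trunk-mounted IMU traces), then ramps at `droop_rate` (defaults 15°/s; a
  failing hold collapses over a second or two). Yaw/pitch carry a tenth of
  the tremor so the attitude problem stays three-dimensional. The analytic
  threshold-crossing time `hold + tolerance/rate` is the timing ground truth.
* **Inverse IMU model**: accelerometer = attitude-rotated gravity reaction,
  gyroscope = finite-difference body rates from the quaternion kinematics,
  magnetometer = attitude-rotated unit field with 50° inclination, each plus
  independent Gaussian noise (CLI defaults 0.05 m/s², 0.002 rad/s, 0.005
  field units — representative of consumer MEMS parts).
* **EMG**: zero-mean Gaussian noise with instantaneous SD
  `baseline + slope·t` (defaults 0.05 mV and 0.0005 mV/s: surface-EMG
  amplitudes during submaximal isometric holds are tens of µV and grow
  slowly as motor units are recruited under fatigue). This is an amplitude
  model only.
* **Paired studies**: subject truths N(mean, σ_b²) observed twice with
  N(0, σ_w²) noise; the population single/average ICCs are returned
  analytically for parameter-recovery experiments.

All generators are bit-reproducible given (scenario, seed) via the PCG64
generator.

What passing tests on these data do **not** show about real recordings: no
soft-tissue artifact, sensor misplacement, magnetic disturbance transients,
gyroscope bias drift, motor-unit structure (spectral content) in the EMG,
or non-constant droop dynamics. The agreement statistics, by contrast, run
on real measured durations from the bundled validation dataset.

## Problem sizes and verification

The test suite verifies timing fidelity on 100 randomized hold/droop
scenarios (durations matching analytic crossings to one sample period), the
EMG identities on 1,000 random epochs, and 95% CI coverage of the one-way
ICC on 500 simulated studies of n = 200 subjects at true average-measures
ICC 0.90 (coverage required ≥ 93%). The whole suite runs in well under a
minute on one core.

## Known limitations

* The fusion filter assumes quasi-static motion between samples; rapid
  whole-body rotation between 51.2 Hz samples would alias the gyro term.
* Normative bins and ratios are fixed constants from the adult reference
  literature; no age/sex stratification is modelled.
* k is fixed at 2 raters/methods throughout the reliability module.
* EMG metrics are time-domain amplitudes only; spectral fatigue indices
  (median frequency shift) are not implemented.
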