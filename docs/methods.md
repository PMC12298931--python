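# Methods

This note documents the models, conventions and numerical choices behind
`gaitaccel`, and what the synthetic testbed does and does not establish.

## Problem and frames

A 9-axis IMU (3-axis gyroscope, accelerometer, magnetometer) strapped to the
anterior mid-shank reads, on its accelerometer, a mixture of signals: the
acceleration generated by walking and the gravity vector as seen by the tilted
sensor. Separating them — and further splitting the motion-generated part into
knee-rotation terms and whole-body translation — is the package's purpose.

Frames and conventions:

* **Sensor frame**: x lateral, y anterior, z along the shank, down positive.
* **Reference frame**: right-handed, z vertical, oriented so gravity is
  `g_o = (0, 0, +g)` with `g = 9.8 m/s²` by default (configurable); at the
  standing calibration pose the two frames coincide.
* **Pose**: roll `φ` / pitch `θ` / yaw `ψ` about reference x / y / z,
  counterclockwise positive; `R0 = Rz(ψ) Ry(θ) Rx(φ)` maps sensor to
  reference coordinates, so a reference vector appears to the sensor as
  `R0ᵀ v`. Radians in memory, degrees at every file boundary.

## Accelerometer decomposition

With `r` the (fixed) offset from the knee-joint center to the sensor,
expressed in the sensor frame, the accelerometer output is

```
A = A_tra + A_cen + A_tan + A_col + g_i
A_cen = ω × (ω × r)          centrifugal         (gyroscope)
A_tan = ω̇ × r                tangential          (differentiated gyroscope)
A_col = 2 ω × ṙ = 0          Coriolis            (r constant on the segment)
g_i   = R0ᵀ (0, 0, g)        gravity             (estimated pose)
A_tra = A − (A_cen + A_tan + g_i)   translational (remainder)
```

The translational term is the knee-center acceleration in sensor coordinates
and carries the motion of segments proximal to the shank. Because it is
defined as the remainder, the five components sum to the raw signal to
machine precision on every sample — this conservation identity is asserted
in the tests and audited by the pipeline on every output table.

The Coriolis field is kept in the data structure, identically zero, so the
assumption is visible rather than silent.

Default geometry: `r = (0, −0.05, −0.2025) m` — the midpoint of the
measured placement range `r_z ∈ [−0.215, −0.190] m` with the sensor 5 cm
anterior of the knee center; overridable per subject.

## Gyroscope differentiation

The angular acceleration comes from the gyroscope through the
pseudo-differentiator `D(s) = s / (1 + n s)` with time constant
`n = 0.01 s`. Two discrete realizations are provided:

* **Zero-phase (default).** Gait records are processed offline, so causality
  buys nothing while the causal filter's group delay (≈ n = 10 ms) converts
  directly into tangential-acceleration error an order of magnitude above the
  attenuation error. The default realization applies the exact magnitude
  response `|D(jω)| = ω / √(1 + (nω)²)` at zero phase in the frequency
  domain, on a full even (mirror) extension of the record so the periodic
  filter sees no wrap-around jump. A raised-cosine roll-off over the top
  half of the digital band (50–100 % of Nyquist at 100 Hz sampling, two
  decades above gait content) suppresses band-edge Gibbs ringing. Residual
  error on band-limited signals is the magnitude attenuation
  `≈ (nω)²/2` per harmonic.
* **Causal (option).** Bilinear (Tustin) transform of `D(s)` at the record's
  sampling interval, initialized at the first sample, for streaming use.

Both realizations reproduce the analytic 1 Hz gain to well under 1 % and
converge to the ideal derivative as `n → 0`. The first `⌈5 n / dt⌉` samples
(and, for the zero-phase variant, the mirrored tail) are flagged as transient
so downstream statistics can exclude them.

## Pose estimation

The extended Kalman filter state is `x = (ψ, θ, φ)`. The state map is one
forward-Euler step of the Euler-rate kinematics driven by the gyroscope
(`sec θ` / `tan θ` terms clamped at |pitch| = 89° with a logged warning;
shank pitch in gait stays far from gimbal lock). The 4-dimensional
observation stacks the tilt-compensated compass heading
`ψ_m = atan2(−m_c_y, m_c_x)`, with `m_c = Ry(θ) Rx(φ) m` computed from the
*predicted* attitude, and the three accelerometer axes, whose noise-free
prediction is `R0ᵀ g_o = g(−sin θ, sin φ cos θ, cos φ cos θ)`. Heading
innovations are wrapped to (−π, π]. Jacobians are analytic and verified
against central finite differences.

Initialization averages the standing head of the record (protocol: 5 s) and
inverts the gravity direction for roll/pitch and the de-tilted field for yaw,
with two-argument arctangents throughout. A warning is recorded if the
calibration window is not quiescent (gyro RMS > 0.05 rad/s). Initial
covariance `P0 = diag((10°)², (5°)², (5°)²)` in state order — the accuracy
scale of accelerometer/magnetometer initialization.

### Adaptive noise covariances

* Process: `Q = (a·|ω|² + b) I₃`. Rotation excites the model error of the
  kinematic integration, so the process noise grows with the squared gyro
  norm; `b > 0` is the floor.
* Observation: `R = diag(Ω_m, Ω_a, Ω_a, Ω_a)` with
  `Ω_m = c·(|m_c|² − m̄) + d` and `Ω_a = e·(Ax² + Ay² + (Az − g)²) + f`.
  The gravity observation is distrusted exactly when the specific force
  deviates from rest — i.e. when motion acceleration contaminates it — and
  the heading observation when the field power deviates from its record
  average `m̄` (magnetic disturbance). `m̄` is the time-average of the
  squared corrected-field norm (equal to the raw norm; the de-tilt matrix is
  a rotation); a norm-based variant is configurable since either reading is
  defensible. All variances are floored at `ε = 1e−9` to keep `Q`, `R`
  positive definite; floor hits are counted.

Default coefficients (overridable, and tunable by maximum likelihood):
`a = 1e−8, b = 1e−9` — per-step integration-error scale of a quiet MEMS
gyro at 100 Hz; `c = 0.05, d = 1e−2` — heading variance floor of ≈ 6°,
mild disturbance scaling; `e = 5, f = 1` — the gravity observation is worth
≈ 1 m/s² at quiet stance and is switched off, in effect, during swing where
the specific-force deviation reaches several m/s². These values were chosen
from the physical scales above; the tuner exists precisely because real
sensors differ.

### Log-likelihood tuning

The innovation log-likelihood

```
LL = −(N·dim/2)·ln 2π − ½ Σ_j [ ln det B_j + V_jᵀ B_j⁻¹ V_j ]
```

is maximized over `(a…f)`. (The scalar per-dimension form quoted for
diagonal `B` is the special case of this multivariate form.) The optimizer
is derivative-free simplex (Nelder–Mead) on log-parameters — positivity by
construction — seeded by a method-of-moments warm start that regresses
squared innovations from one filter pass onto the adaptation regressors.
After each simplex run, every coefficient is probed at ×10 and ÷10; an
improving probe restarts the simplex there. The best parameters evaluated
anywhere are returned, so the tuned likelihood never falls below the
starting one; non-convergence within the evaluation budget returns the best
found with a warning. All six coefficients are tuned jointly (the staged
alternative is a trivial restriction of the same code path).

Two properties of this criterion matter for interpretation:

* On *noiseless* synthetic records the ML noise estimates collapse toward
  zero and the likelihood is unbounded — tuning is only meaningful on
  records with sensor noise.
* The likelihood rewards small, well-calibrated innovations, which an
  observation-following filter can achieve on smooth records; on this
  simulator's deterministic motion the ML optimum therefore does not
  coincide with the minimum pose error, and the physically scaled defaults
  track the simulated truth better than the tuned values. The tuner is
  validated by its own contract — monotone improvement and ×10-local
  optimality — not by pose error. On real sensors, whose errors are closer
  to the white-noise model the likelihood assumes, ML tuning is the
  appropriate calibration; this gap is a limitation of the synthetic
  testbed, not of the estimator.

## Gait-cycle analysis

Cycles run contact → contact; stance ends at toe-off. Each cycle is mapped
to a 0–100 % grid (101 points; the sources plot percent cycle without
stating a resolution) anchored at the *average* toe-off percentage across
cycles: stance and swing are linearly resampled onto the grid segments on
either side of the anchor, so every cycle's stance/swing boundary lands on
the same grid point before averaging. Ensembles report pointwise mean and
sample SD (n−1); a single cycle yields SD 0 with a warning. Phase
statistics (Pearson r and RMSE between two channels over a % window) are
computed per cycle and summarized mean ± SD, matching the field's
"0.50 ± 0.28" reporting style; stance defaults to [0 %, toe-off] and swing
to (toe-off, 100 %], with sub-phase windows configurable (the conventional
qualitative sub-phases have no universal numeric boundaries).

Event detection from the sagittal shank angular velocity is provided as
plumbing for records without annotations: the waveform's dominant mid-swing
peak is flanked by troughs marking toe-off (before) and the next contact
(after). The signal is auto-oriented, peaks are found at the record's
dominant cadence (rejected outside 0.5–2 Hz), troughs are searched within a
quarter cycle of each peak and refined by parabolic interpolation.
Externally annotated events always take precedence.

## Synthetic gait

The generator emulates the measurement protocol — 5 s standing, a one-cycle
ramp into steady walking at 90 steps/min (cycle 4/3 s), stride 1.5 m
(1.125 m/s, inside the protocol's observed 1.05–1.2 m/s) — with a
closed-form, infinitely differentiable kinematic model so every derivative
is exact:

* The shank's sagittal angular-velocity profile is a 4-harmonic Fourier
  series fitted once to the canonical shank-gyro template (dominant positive
  mid-swing peak, troughs at the events) under analytic constraints placing
  its two troughs exactly at foot contact (0 %) and toe-off (60 %) with a
  −1.10 rad stance excursion; these troughs *define* the ground-truth
  events. The band limit (3 Hz) is deliberate: it keeps the waveform inside
  the differentiator's stated resolution.
* The hip angle is a single-harmonic sagittal oscillation (23° flexion at
  contact to −10° extension); the implied knee angle stays in a
  physiological −3°…46° range with peak flexion in mid-swing.
* Small frontal (2°) and transverse (4°) shank oscillations exercise pitch
  and yaw; the pelvis translates forward with ±2 cm vertical (2/cycle) and
  ±3 cm lateral (1/cycle) oscillations.
* A C² quintic smoothstep envelope blends standing into gait.

Body rates follow from the exact Euler-rate inverse kinematics; the
knee-center world acceleration from analytic second derivatives; the ideal
accelerometer signal from the component model itself, so the synthesized
components satisfy the conservation identity by construction. The
magnetometer reads a unit reference field (horizontal by default, dip
configurable) rotated into the sensor frame. Sensor imperfections are
optional seeded Gaussian noise (gyro/accel/mag) and a constant gyro bias;
`with_sensor_noise()` applies a realistic preset (0.01 rad/s, 0.1 m/s²,
1 % of field).

What the simulator does *not* emulate — and what passing tests therefore do
not establish for real data: soft-tissue artifact, sensor misalignment and
hard/soft-iron magnetic distortion, gyro bias drift, impact transients at
heel strike (the band limit removes them), inter-subject waveform
variability, and any non-sagittal-dominant pathology. Recovery numbers on
synthetic gait are a verification of the algorithm chain, not a clinical
validation.

## Problem sizes and numerical choices

The standard test conditions are 10 steady cycles (≈ 20 s at 100 Hz) for
noiseless recovery checks and 3 cycles with sensor noise for tuning; these
sizes put every identity at machine precision and every recovery statistic
well inside its tolerance while keeping the full suite and the acceptance
script fast. Other fixed choices: covariance symmetrization after every
update, state covariance validated symmetric PSD to 1e−9; heading innovation
wrapped, state angles left unwrapped for continuity; linear interpolation
for cycle resampling (the 1 % grid is dense relative to 100 Hz sampling);
config-hash stamping of every output table for provenance.

## Known limitations

* Euler-angle state: unsuitable for |pitch| near 90° (irrelevant for shank
  gait, guarded regardless).
* The knee-center offset `r` is treated as rigid; soft-tissue motion
  violates this on real legs.
* ML noise tuning inherits the innovation-likelihood blind spots described
  above.
* Event detection is a heuristic for convenience; validated gait-event
  timing should come from instrumented walkways or annotation.
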