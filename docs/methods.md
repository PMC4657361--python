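# Methods

This note documents the models, conventions and numerical choices behind
`gaitdisp`, what the synthetic generator does and does not emulate, and the
known limitations.

## Frames and conventions

* **GGF** (global gravity-aligned frame): X antero-posterior (forward),
  Y medio-lateral (right), Z vertical **positive down**; gravity is
  (0, 0, +9.81) m/s². Traces are always reported in the axis order ML, VT,
  AP.
* **Quaternions** are scalar-first Hamilton, rotating sensor-frame vectors
  into the GGF (`v_global = R(q) v_body`). Series are kept sign-continuous.
* **Euler angles** for reporting are intrinsic Z–Y–X (yaw, pitch, roll) on
  the Z-down frame.
* Internal units are SI throughout (m, m/s², rad, s); millimetres and
  degrees appear only at reporting boundaries.

## Orientation estimation

A minimal 4-state quaternion EKF:

* **Propagation** q̇ = ½ q ⊗ (0, ω) with the bias-corrected gyro rates,
  discretised exactly per sample as q ← q ⊗ exp(½ ω Δt). Process noise
  follows from the gyro angular random walk
  (`gyro_noise_density`, default 3.5e-4 rad/s/√Hz at 100 Hz).
* **Measurement** is the raw specific force with predicted value
  h(q) = −R(q)ᵀ g. Using the unnormalised force matters: gait-phase-locked
  linear acceleration is zero-mean over a stride, so its corruption averages
  out, whereas normalising the measured direction introduces a bias whenever
  the linear acceleration is comparable to g (fast walking). The measurement
  noise (`accel_meas_noise`, default 2 m/s²) deliberately budgets the linear
  acceleration, making the updates a slow, unbiased trim of the tilt; an
  update is skipped when ||f| − g| exceeds `accel_gate` (default 6 m/s²).
* **Bias**: the constant gyro bias is the mean gyro reading over the
  standing-rest prefix and is subtracted up front; no bias state is kept. No
  scale-factor correction is applied.
* **Initial attitude** aligns roll/pitch with the mean rest-period specific
  force (rejected if its norm deviates >5% from g); yaw starts at 0 because
  heading is unobservable without a magnetometer. Consequently the yaw
  "error" against a reference is dominated by the unknown initial heading —
  the same situation as any magnetometer-free setup — and is a few degrees,
  while roll/pitch errors stay well under ~1°. The EKF tuning values are
  exposed in `OrientationFilterParams` since no canonical values exist for
  this filter family.

## Stride segmentation

* **Shank** (primary): the ML shank angular velocity is low-passed at 5 Hz;
  positive mid-swing peaks are those above 50°/s and above 0.5× the median
  qualifying peak, at least 0.5 s apart; the heel strike is the first local
  minimum within 0.4 s after each swing peak. Stride durations outside
  [0.4, 2.5] s are rejected.
* **Trunk** (heuristic alternative): step peaks are detected on the
  low-passed AP linear acceleration (two per stride); right-side events are
  selected as the peak parity with the larger mean amplitude (falling back
  to the steadier inter-event interval). The fiducial has a constant phase
  offset from the anatomical heel strike; stride *durations* are unaffected,
  which is all the downstream processing needs.
* **Variability** is reported as 100·SD/mean with the population SD
  (divide by n).

## Per-stride Fourier model and analytic integration

Coefficients are estimated by ordinary least squares on the basis
{1, cos(2πkt/T), sin(2πkt/T)}, k = 1..N (default N = 20), at the actual
sample times — exact on uniform grids and robust to non-integer
samples-per-stride. When a stride holds fewer than 2N+1 samples the order is
reduced to ⌊(M−1)/2⌋ with a warning. The stride-local time origin is the
detected heel strike.

Integration drops the constant term (cyclical movement ⇒ zero-mean
acceleration) and maps coefficients in closed form; the per-stride velocity
and displacement are therefore *mean-subtracted by construction* and immune
to integration drift. Fit adequacy is monitored by the normalized RMSD
(100·RMS(residual)/RMS(signal)); values below 5% are considered adequate.

Stride boundaries carry step discontinuities (segmentation jitter,
orientation error), so the truncated series overshoots there by the Gibbs
constant (≈9% of the jump, order-independent; asymptotically
(1/π)Si(π) − 1/2 ≈ 0.0895). The ripples sit at frequency ≈ N/T and are
attenuated by 1/k² in the displacement, leaving sub-millimetre artefacts.

The acceleration is zero-phase low-pass filtered at 12 Hz (second-order
Butterworth, forward–backward) before any integration, uniformly for all
method variants.

## Concatenation of stride traces

Reconstructed strides need not match at the boundaries. Rather than
smoothing the whole concatenated trace — which cannot both preserve the
gait band and flatten millimetre jumps — the implementation estimates each
boundary jump from local finite differences (quadratic extrapolation of the
increments from both sides), accumulates the jumps into a staircase, smooths
the staircase with a cubic smoothing spline, and subtracts
(staircase − smoothed staircase). Properties:

* continuous input passes through bit-identically (jumps below 10× the
  median second-difference noise floor are ignored);
* only boundary neighbourhoods are touched;
* the smoothing parameter (`spline_smoothing_hz`, default 0.35 Hz
  equivalent; λ = Δt/(2πf)⁴) is calibrated so that ≲10% of a boundary jump
  survives as the residual sample-to-sample increment — a 5 mm jump leaves
  <0.5 mm.

## Comparator integrators

* **Windowed trapezoid**: per stride, the mean over [stride i−1, stride i+1]
  is subtracted (one-sided windows at the edges), then trapezoidal
  integration; the mean subtraction is repeated on the velocity, and the
  displacement is per-stride mean-removed for comparability.
* **High-pass + trapezoid**: zero-phase second-order Butterworth high-pass
  (0.5 Hz ML, 1 Hz VT/AP) interleaved with two trapezoidal integrations and
  applied once more to the displacement (3 passes; a 1-pass variant is
  configurable).

## Agreement statistics

Constant limits of agreement use MD ± 1.96·SD of the differences
(population SD). The regression variant fits the difference D and the
absolute residuals |r| on the pair mean A by least squares; limits are
D̂(A) ± 2.46·R̂(A), with 2.46 = √(π/2)·1.96 converting the mean absolute
residual of a normal into its SD-based band. The representative width
averages 2·2.46·R̂(A) over the central 95% of A. All agreement statistics
are computed on steady-state strides only: strides fully inside the
recording minus 30 s at each end, with stride-based piecewise-constant trend
removal applied to *both* the estimate and the reference — which is why MD
is structurally ≈0 for the stride-based methods. The high-pass method has no
segmentation of its own and is detrended with the shank-based segmentation
when available.

## Synthetic generator

The generator emulates the validation protocol: 2-min treadmill trials at
3–7 km/h, 5-s standing rest, 100 Hz sampling. Study conditions per speed
(stride-time mean/CV, per-axis displacement peak-to-trough, angular ranges
of motion) are fixed calibration tables in `synth.SPEED_CONDITIONS`.

* **Displacement** per axis is a fixed harmonic recipe of the stride phase —
  ML dominated by the stride frequency, VT/AP by the step frequency (2× the
  stride frequency) with a small once-per-stride asymmetry that
  distinguishes right from left steps — scaled to the peak-to-trough
  targets, plus a slow non-periodic horizontal sway (sum of 4 random slow
  sinusoids; default SD 6 mm, corner 0.08 Hz). All recipes use ≤6 harmonics,
  well inside the order-20 model class.
* **Orientation** sways periodically within the configured ranges around a
  small standing tilt (roll 1°, pitch 4°); an optional slow roll ramp
  (`tilt_drift_deg`) emulates postural drift. Body rates follow from the
  exact Euler-rate kinematics.
* **Sensors**: the trunk specific force is computed analytically as
  R(q)ᵀ(a − g) from the ground-truth kinematics, then white noise
  (0.02 m/s² SD) is added; gyros get white noise (0.2°/s SD) plus a constant
  random-direction bias (0.5°/s). The shank ML gyro is a per-stride template
  with a mid-swing positive peak, a toe-off dip and a sharp minimum at the
  true heel strike. Stride durations are truncated-normal (±3 SD). The rest
  prefix is pure gravity. Everything is reproducible from one seed.

**What the generator does not emulate** — and hence what passing tests do
not establish about real recordings: soft-tissue artefacts and sensor
mounting compliance; waveform variability from stride to stride (the
harmonic recipe is fixed); *step-level* timing variability (left and right
step times are rigidly tied to the stride), which is why trunk-based
stride-time variability does not exceed shank-based variability here the
way it does on real walkers; treadmill-belt dynamics and pathological gait.
Real-data agreement bands are therefore expected to be wider than the
synthetic ones, while the structural properties (zero drift, ≈0 bias,
ordering of the method variants) carry over.

## Numerical choices and degenerate inputs

* Zero-phase filtering uses `sosfiltfilt` with odd reflective padding
  (≥3 filter lengths); cut-offs at or above Nyquist are rejected.
* Harmonic fitting requires ≥3 samples; empty or degenerate segmentations
  raise (or warn and return empty, for detectors).
* Time grids must be uniform within 1e-9 s; quaternions unit within 1e-6.
* Bland–Altman needs ≥2 pairs, the regression limits ≥10 pairs and
  non-degenerate pair means.
* The 2-min pipeline (EKF + segmentation + Fourier integration) runs in
  ~2 s on one CPU; the bundled evaluation sizes (five 2-min trials for the
  study-level statistics, 60-s trials for unit-level checks) were chosen to
  keep full-suite runs fast while leaving dozens of strides per trial.
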