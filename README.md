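# gaitdisp

Drift-free estimation of the three-dimensional displacement of a body part
during cyclical motion — here, the lower trunk during walking — from a
body-worn inertial measurement unit (tri-axial gyroscope + accelerometer),
with no optical motion capture required at run time.

## The problem

Double time-integration of accelerometer data ("strap-down integration")
drifts without bound: sensor noise and bias accumulate quadratically in the
displacement. For cyclical movements such as gait there is a way out: over
one stride the linear acceleration is almost periodic, and a periodic signal
can be integrated *analytically* instead of numerically.

## The method

1. **Orientation.** A quaternion extended Kalman filter propagates the trunk
   orientation from the gyroscope and corrects roll/pitch with the
   accelerometer's gravity observation (no magnetometer; heading is
   unobservable). The constant gyro bias is captured during a 5-s standing
   rest and subtracted.
2. **Strap-down rotation.** The measured specific force **f** is rotated into
   the gravity-aligned global frame and gravity-compensated:
   **a** = R(q)·**f** + **g**, giving the linear acceleration on the
   medio-lateral (ML), vertical (VT) and antero-posterior (AP) axes.
3. **Stride segmentation.** Heel strikes of the instrumented leg are detected
   from the mid-swing peak of the shank's ML angular velocity (alternatively
   from trunk AP acceleration peaks).
4. **Per-stride Fourier model.** Each axis of the i-th stride is fitted by
   least squares with a truncated Fourier series (order N = 20),

   acc(t) = a(0) + Σₖ [ a(k)·cos(2πkt/Tᵢ) + b(k)·sin(2πkt/Tᵢ) ],

   where Tᵢ is the stride duration.
5. **Analytic integration.** Dropping a(0) (a cyclical movement has zero-mean
   acceleration), velocity and displacement follow in closed form; the
   mean-subtracted stride displacement is

   displ(t) = −(Tᵢ/2π)² Σₖ (1/k²) [ a(k)·cos(2πkt/Tᵢ) + b(k)·sin(2πkt/Tᵢ) ],

   which cannot drift. Stride traces are concatenated and boundary
   discontinuities are smoothed with a cubic smoothing spline.

Comparator variants are included: motion-capture reference rotation
(baseline), constant initial rotation (B), trunk-accelerometer segmentation
(C), windowed-mean-subtraction trapezoidal integration (D), and high-pass
filtering + trapezoidal integration with per-axis cut-offs 0.5 Hz (ML) and
1 Hz (VT, AP) (E). Agreement between any two displacement estimates is
quantified with Bland–Altman statistics: mean difference (MD), limits of
agreement (LA = MD ± 1.96·SD of differences), and regression-based limits
D̂(A) ± 2.46·R̂(A) for non-uniform differences.

Because no recorded dataset ships with the package, a synthetic treadmill
simulator (`gaitdisp.synth`) generates 2-min trials at 3–7 km/h with a 5-s
standing rest, published stride-time statistics, displacement amplitudes and
angular sway ranges, sensor noise and gyro bias — together with the exact
ground-truth orientation and displacement, so the whole pipeline is testable
end to end.

## Worked example

```python
from gaitdisp import (RunConfig, TrialConfig, agreement_report,
                      generate_trial, method_vs_reference)
from gaitdisp.pipeline import Trial

trial = generate_trial(TrialConfig(speed_kmh=5, seed=12))   # 2-min, 5 km/h
est_mm, ref_mm, seg = method_vs_reference(Trial.from_synthetic(trial), "A")
print(agreement_report(est_mm, ref_mm).summary())
```

prints

```
axis      MD (mm)   LA half-width (mm)   LA width (mm)
ml          0.0000              1.805           3.610
vt          0.0000              1.056           2.113
ap         -0.0000              1.614           3.227
```

The bias (MD) is structurally negligible after stride-based detrending of
both traces, and the 95% agreement band with the simulator's ground truth is
1–2 mm per axis over the 63 steady-state strides — no drift accumulates even
though the displacement comes from doubly integrated accelerometer data.
The `examples/` directory walks through each capability (simulation,
estimation, method comparison, Gibbs/fit adequacy, Bland–Altman regression).

## Command line

```bash
gaitdisp simulate --speed 5 --seed 42 --out-dir trial/
gaitdisp run --method A --imu trial/trunk.csv --shank trial/shank.csv --out displ.csv
gaitdisp compare --imu trial/trunk.csv --shank trial/shank.csv \
    --ref-displ trial/truth_displ.csv --out comparison.csv
gaitdisp report --imu trial/trunk.csv --shank trial/shank.csv \
    --ref-displ trial/truth_displ.csv --method A --out-dir report/
```

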