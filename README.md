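# imugait

Gait analysis from body-worn inertial sensors (IMU/MARG: accelerometer +
gyroscope + magnetometer) on the feet, shanks and thighs.  The package
implements the full measurement chain a wearable gait-analysis system
needs, and a parametric gait simulator with ground truth that closes the
loop for every claim the package makes.

Clinical context: spatio-temporal gait parameters (stride length, speed,
cadence, stance/swing times, foot clearance) and knee range of motion
(ROM) quantify walking disorders — for example the bilateral asymmetry of
hemiplegic stroke patients — objectively and outside a motion-capture lab.

## What it computes

1. **Sensor calibration by constrained ellipsoid fitting.**
   A triad with small inter-axis misalignment measures, at rest, gravity
   through the distortion `E ≈ [[1,0,α],[β,1,γ],[0,0,1]]`, so static
   multi-orientation samples lie on an ellipsoid
   `(x−b)ᵀ E⁻ᵀE⁻¹ (x−b) = g²`.  The quadric coefficients
   `O = (a,b,c,f,g,h,p,q,r,d)` are fitted by least squares under the
   ellipsoid-guaranteeing constraint `OᵀMO = 1` (a generalized
   eigenproblem), and the misalignment angles follow in closed form from
   the quadratic form.  The same fit applied to a figure-eight
   magnetometer sweep yields the hard-iron offset (ellipsoid centre) and
   the soft-iron correction (symmetric square root mapping the ellipsoid
   to a sphere).

2. **Attitude by a PI complementary filter.**
   Body rates are integrated through the quaternion kinematics
   `q̇ = ½ q ⊗ (0, ω)`; gravity and magnetic-field measurements correct
   the drift via error vectors `e = v̂_meas × v̂_pred` fed back as
   `ω' = ω + k_p e + k_i ∫e dt`.  Gravity aiding is gated to quiescent
   samples; the magnetic correction is projected to act on heading only.

3. **Zero-velocity-aided dead reckoning (ZVU / ZUPT).**
   Stance is detected per sample from the moving variance of the
   normalised acceleration norm and the windowed angular-rate energy
   (`stance ⇔ variance < λ₁ ∧ energy < λ₂`).  The specific force is
   rotated to the global frame, gravity subtracted, and integrated twice;
   velocity is clamped to zero in stance and the residual at each stance
   onset is redistributed linearly over the preceding swing, which cancels
   any constant acceleration error per stride exactly.

4. **Gait parameters and symmetry statistics.**
   Strides (initial contact → next initial contact), stride
   length/speed/frequency, stance/swing times, swing clearance, knee and
   ankle angle series by gyro-difference integration
   (`θ_knee = ∫(ω_thigh−ω_shank)dt + θ_thigh,0 − θ_shank,0`), knee ROM per
   stride, and a one-way ANOVA of bilateral knee ROM (strides paired by
   index: k pairs → F on (k−1, k) degrees of freedom).

## Worked example

```python
import numpy as np
from imugait.simulate import (GaitModelConfig, SensorErrorModel, simulate_truth,
                              synthesize_imu, static_orientation_cloud, figure_eight_sweep)
from imugait.calibration import calibrate_accelerometer, calibrate_magnetometer
from imugait.pipeline import PipelineConfig, run_pipeline

truth = simulate_truth(GaitModelConfig(n_strides=10))       # healthy-adult defaults
err = SensorErrorModel(seed=3)                              # MEMS noise + distortions
seqs = synthesize_imu(truth, err)                           # six raw sensor streams

accel_cal = calibrate_accelerometer(static_orientation_cloud(err))
mag_cal = calibrate_magnetometer(figure_eight_sweep(err))
report = run_pipeline(seqs, PipelineConfig(accel_cal=accel_cal, mag_cal=mag_cal))

for name, (mean, sd) in report.sides["L"].parameters.summary().items():
    print(f"{name:16s} {mean:8.4f} ± {sd:.4f}")
print("bilateral knee-ROM ANOVA: F =", round(report.anova.f, 2))
```

prints (simulated ground truth: stride 1.21 m, cycle 1.32 s, clearance
0.22 m, knee ROM 59.0°):

```
stride_length      1.2098 ± 0.0004
stride_speed       0.9165 ± 0.0003
stride_frequency  90.9091 ± 0.0000
walking_cycle      1.3200 ± 0.0000
stance_time        0.8856 ± 0.0053
swing_time         0.4344 ± 0.0053
clearance          0.2194 ± 0.0001
knee_rom          58.9992 ± 0.0914
bilateral knee-ROM ANOVA: F = 1.07
```

Every parameter lands on the simulated truth within a fraction of a
percent; the ANOVA is unremarkable because the simulated gait is
symmetric.

The same pipeline is scriptable from the shell:

```bash
imugait simulate --outdir session --strides 10 --seed 3
imugait calibrate --accel-cloud session/accel_cloud.csv \
                  --mag-sweep session/mag_sweep.csv --out cal.yaml
imugait analyze --indir session --calibration cal.yaml --outdir report
imugait report --report-dir report
```

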