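"""Ellipsoid fitting, misalignment-angle extraction, magnetometer calibration."""

import numpy as np
import pytest

from imugait.calibration import (
    MagCalibration,
    NonOrthoAngles,
    apply_accel_calibration,
    apply_mag_calibration,
    calibrate_accelerometer,
    calibrate_magnetometer,
    correct_accel,
    ellipsoid_geometry,
    estimate_nonortho_angles,
    fit_ellipsoid,
    nonortho_matrix,
)
from imugait.errors import FitError, InvalidInputError
from imugait.simulate import (
    MAGNETIC_FIELD,
    SensorErrorModel,
    figure_eight_sweep,
    static_orientation_cloud,
)

TRUE_ANGLES = NonOrthoAngles(*np.radians([0.5, 0.3, 0.8]))


def unit_directions(n, seed=0):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n, 3))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


class TestEllipsoidFit:
    def test_unit_sphere_degenerate_case(self):
        model = fit_ellipsoid(unit_directions(50))
        center, radii, axes = ellipsoid_geometry(model)
        assert np.allclose(center, 0.0, atol=1e-8)
        assert np.allclose(radii, 1.0, atol=1e-8)
        a, b, c, f, g, h = model.coeffs[:6]
        assert abs(a - b) < 1e-8 and abs(b - c) < 1e-8
        assert max(abs(f), abs(g), abs(h)) < 1e-8

    def test_axis_aligned_ellipsoid_recovery(self):
        """Exact points on radii (1,2,3) about an offset centre."""
        pts = unit_directions(100) @ np.diag([1.0, 2.0, 3.0]) + np.array([0.1, -0.2, 0.3])
        center, radii, _ = ellipsoid_geometry(fit_ellipsoid(pts))
        assert np.allclose(center, [0.1, -0.2, 0.3], atol=1e-6)
        assert np.allclose(radii, [1.0, 2.0, 3.0], rtol=1e-6)

    def test_constraint_satisfied(self):
        """The quadric coefficient vector satisfies the unit constraint."""
        err = SensorErrorModel(seed=11)
        model = fit_ellipsoid(static_orientation_cloud(err, 32, 20))
        assert abs(model.constraint_value - 1.0) < 1e-9

    def test_rotated_axes_recovery(self):
        th = np.radians(30)
        Rz = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        pts = unit_directions(120, seed=3) @ (Rz @ np.diag([1.0, 2.0, 2.5])).T
        _, radii, axes = ellipsoid_geometry(fit_ellipsoid(pts))
        assert np.allclose(sorted(radii), [1.0, 2.0, 2.5], rtol=1e-6)
        # recovered axes match the applied rotation up to column sign
        assert np.allclose(np.abs(axes.T @ Rz), np.eye(3), atol=1e-6)

    def test_transformed_points_on_standard_form(self):
        """Centre/axes transformation maps points to x²/a′²+y²/b′²+z²/c′²=1."""
        pts = unit_directions(80, seed=7) @ np.diag([2.0, 1.5, 1.0]) + 0.3
        center, radii, axes = ellipsoid_geometry(fit_ellipsoid(pts))
        local = (pts - center) @ axes
        lhs = np.sum((local / radii) ** 2, axis=1)
        assert np.allclose(lhs, 1.0, atol=1e-6)

    @pytest.mark.parametrize("radii", [(1, 1.5, 2), (1, 3, 5), (1, 1, 4.9)])
    def test_recovery_up_to_ratio_five(self, radii):
        pts = unit_directions(100, seed=9) @ np.diag(radii)
        _, got, _ = ellipsoid_geometry(fit_ellipsoid(pts))
        assert np.allclose(sorted(got), sorted(radii), rtol=1e-6)

    def test_degenerate_cloud_raises(self):
        rng = np.random.default_rng(0)
        planar = np.column_stack([rng.normal(size=40), rng.normal(size=40), np.zeros(40)])
        with pytest.raises(FitError):
            fit_ellipsoid(planar)

    def test_too_few_points(self):
        with pytest.raises(InvalidInputError):
            fit_ellipsoid(np.ones((5, 3)))


class TestNonOrthoAngles:
    def test_perfect_sensor_zero_angles(self):
        pts = unit_directions(200) * 9.81
        got = estimate_nonortho_angles(fit_ellipsoid(pts))
        assert max(abs(a) for a in got) < 1e-9

    def test_noiseless_recovery(self):
        """Injected (0.5, 0.3, 0.8) deg recovered to 0.02 deg without noise."""
        E = nonortho_matrix(TRUE_ANGLES)
        pts = (unit_directions(200) * 9.81) @ E.T
        got = estimate_nonortho_angles(fit_ellipsoid(pts))
        assert np.allclose(np.degrees(got), [0.5, 0.3, 0.8], atol=0.02)

    def test_noisy_recovery_monte_carlo(self):
        """Sensor-noise-scale recovery stays within 0.1 deg over 20 seeds."""
        worst = 0.0
        for seed in range(20):
            err = SensorErrorModel(seed=seed, accel_bias=0.0)
            cloud = static_orientation_cloud(err, n_orient=64, samples_per_orientation=50)
            got = estimate_nonortho_angles(fit_ellipsoid(cloud))
            worst = max(worst, np.max(np.abs(np.degrees(got) - [0.5, 0.3, 0.8])))
        assert worst < 0.1

    def test_noise_response_monotone(self):
        """Angle RMSE grows with accelerometer noise (0 < 0.01 < 0.05 m/s²)."""
        rmses = []
        for sd in (0.0, 0.01, 0.05):
            errs = []
            for seed in range(5):
                err = SensorErrorModel(
                    seed=seed, accel_noise_sd=sd, accel_bias=0.0
                )
                cloud = static_orientation_cloud(err, n_orient=32, samples_per_orientation=20)
                got = estimate_nonortho_angles(fit_ellipsoid(cloud))
                errs.append(np.degrees(np.array(got)) - [0.5, 0.3, 0.8])
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] < rmses[1] < rmses[2]


class TestCorrectAccel:
    def test_zero_angles_identity(self, rng):
        v = rng.normal(size=3)
        assert np.allclose(correct_accel(v, NonOrthoAngles(0, 0, 0)), v)

    def test_forward_model_round_trip(self, rng):
        E = nonortho_matrix(TRUE_ANGLES)
        for _ in range(20):
            v = rng.normal(size=3) * 9.81
            back = correct_accel(E @ v, TRUE_ANGLES)
            assert np.linalg.norm(back - v) < 2e-4 * np.linalg.norm(v)

    def test_variance_reduction_at_rest(self):
        """Corrected static norms cluster tighter around g than raw ones."""
        angles = NonOrthoAngles(*np.radians([0.5, 0.4, 0.6]))
        E = nonortho_matrix(angles)
        raw = (unit_directions(300, seed=2) * 9.81) @ E.T
        corrected = correct_accel(raw, angles)
        var_raw = np.var(np.linalg.norm(raw, axis=1))
        var_cor = np.var(np.linalg.norm(corrected, axis=1))
        assert var_cor < var_raw

    def test_full_calibration_restores_bias_and_angles(self):
        err = SensorErrorModel(seed=5, accel_noise_sd=0.0)
        cal = calibrate_accelerometer(static_orientation_cloud(err, 32, 1))
        E = nonortho_matrix(err.nonortho)
        bias, _ = err.bias_vectors("foot_L")
        v = np.array([3.0, -4.0, 8.0])
        restored = apply_accel_calibration(E @ v + bias, cal)
        assert np.linalg.norm(restored - v) < 1e-3 * np.linalg.norm(v)


class TestMagnetometer:
    def test_undistorted_identity(self):
        err = SensorErrorModel.ideal()
        cal = calibrate_magnetometer(figure_eight_sweep(err, n_samples=600))
        assert np.allclose(cal.offset, 0.0, atol=1e-6)
        field = np.linalg.norm(MAGNETIC_FIELD)
        assert np.allclose(cal.matrix / field, np.eye(3) / field, atol=1e-6 / field)

    def test_hard_soft_iron_recovery(self):
        """Hard iron (10,-5,3) and diagonal soft iron recovered within 1%."""
        err = SensorErrorModel(seed=2, mag_noise_sd=0.0)
        cal = calibrate_magnetometer(figure_eight_sweep(err, n_samples=2000))
        assert np.allclose(cal.offset, [10.0, -5.0, 3.0], rtol=0.01, atol=0.05)
        # calibration matrix must invert the soft iron up to a uniform scale
        prod = cal.matrix @ err.soft_iron
        scale = np.trace(prod) / 3.0
        assert np.allclose(prod / scale, np.eye(3), atol=0.01)

    def test_calibrated_norm_constant(self):
        """Noiseless distorted sweep maps onto a sphere (CV < 0.5%)."""
        err = SensorErrorModel(seed=4, mag_noise_sd=0.0)
        sweep = figure_eight_sweep(err, n_samples=1500)
        cal = calibrate_magnetometer(sweep)
        norms = np.linalg.norm(apply_mag_calibration(sweep, cal), axis=1)
        assert np.std(norms) / np.mean(norms) < 0.005

    def test_apply_identity_and_offset(self):
        ident = MagCalibration.identity()
        raw = np.array([1.0, 2.0, 3.0])
        assert np.allclose(apply_mag_calibration(raw, ident), raw)
        off = MagCalibration(offset=raw, matrix=np.eye(3))
        assert np.allclose(apply_mag_calibration(raw, off), 0.0)

    def test_round_trip_with_generator(self):
        err = SensorErrorModel(seed=6, mag_noise_sd=0.0)
        sweep = figure_eight_sweep(err, n_samples=2000)
        cal = calibrate_magnetometer(sweep)
        restored = apply_mag_calibration(sweep, cal)
        true_mag = np.linalg.norm(MAGNETIC_FIELD)
        # directions restored; norms uniform at the estimated field strength
        undistorted = (sweep - err.hard_iron) @ np.linalg.inv(err.soft_iron).T
        cosines = np.sum(restored * undistorted, axis=1) / (
            np.linalg.norm(restored, axis=1) * np.linalg.norm(undistorted, axis=1)
        )
        assert np.all(cosines > 1 - 1e-6)
        assert np.allclose(np.linalg.norm(restored, axis=1), true_mag, rtol=0.02)
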