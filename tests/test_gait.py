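"""Strapdown integration with ZVU, stride segmentation, joint angles."""

import numpy as np
import pytest

from imugait.errors import InvalidInputError
from imugait.gait import (
    SegmentAngles,
    compute_gait_parameters,
    initial_segment_angle,
    integrate_position_zvu,
    knee_angle,
    ankle_angle,
    knee_rom,
    register_trajectory,
    remove_gravity,
    segment_strides,
)
from imugait.quaternion import quat_identity
from imugait.sequence import GRAVITY, ImuSequence
from imugait.simulate import GaitModelConfig, SensorErrorModel, simulate_truth, synthesize_imu
from imugait.stance import StanceMask, detect_stance


class TestRemoveGravity:
    def test_stationary(self, rng):
        n = 100
        quats = np.tile(quat_identity(), (n, 1))
        acc = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        assert np.allclose(remove_gravity(acc, quats), 0.0, atol=1e-12)

    def test_free_fall(self):
        quats = np.tile(quat_identity(), (10, 1))
        out = remove_gravity(np.zeros((10, 3)), quats)
        assert np.allclose(out, [0.0, 0.0, -GRAVITY])

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            remove_gravity(np.zeros((10, 3)), np.tile(quat_identity(), (9, 1)))


class TestIntegrateZvu:
    def test_stationary_displacement_negligible(self, rng):
        n = 1000
        acc = rng.normal(0, 0.02, (n, 3))
        mask = StanceMask.from_mask(np.ones(n, dtype=bool))
        _, pos = integrate_position_zvu(acc, mask, 100.0)
        assert np.linalg.norm(pos[-1]) < 1e-3

    def test_single_stride_length(self):
        """One simulated stride: displacement recovered within 2 cm (noiseless)."""
        truth = simulate_truth(GaitModelConfig(n_strides=1))
        seq = synthesize_imu(truth, SensorErrorModel.ideal())["foot_L"]
        mask = detect_stance(seq)
        lin = remove_gravity(seq.acc, truth.segments["foot_L"].quat)
        _, pos = integrate_position_zvu(lin, mask, 100.0)
        assert abs(pos[-1, 0] - 1.21) < 0.02

    def test_single_stride_length_noisy(self):
        """Same recovery within 5 cm under sensor noise, multiple seeds."""
        from imugait.calibration import NonOrthoAngles

        truth = simulate_truth(GaitModelConfig(n_strides=1))
        for seed in range(20):
            err = SensorErrorModel(
                seed=seed,
                nonortho=NonOrthoAngles(0.0, 0.0, 0.0),
                accel_bias=0.0,
                hard_iron=np.zeros(3),
                soft_iron=np.eye(3),
            )
            seq = synthesize_imu(truth, err)["foot_L"]
            mask = detect_stance(seq)
            lin = remove_gravity(seq.acc, truth.segments["foot_L"].quat)
            _, pos = integrate_position_zvu(lin, mask, 100.0)
            assert abs(pos[-1, 0] - 1.21) < 0.05

    def test_zvu_strictly_better_than_none(self, default_truth, noisy_sequences):
        seq = noisy_sequences["foot_L"]
        mask = detect_stance(seq)
        lin = remove_gravity(seq.acc, default_truth.segments["foot_L"].quat)
        _, p_on = integrate_position_zvu(lin, mask, 100.0)
        _, p_off = integrate_position_zvu(lin, mask, 100.0, apply_zvu=False)
        truth_p = default_truth.segments["foot_L"].pos
        truth_p = truth_p - truth_p[0]
        err_on = np.sqrt(np.mean(np.sum((p_on - truth_p) ** 2, axis=1)))
        err_off = np.sqrt(np.mean(np.sum((p_off - truth_p) ** 2, axis=1)))
        assert err_on < err_off

    def test_drift_warning_without_updates(self, rng):
        n = 1200
        acc = rng.normal(0, 0.02, (n, 3))
        mask = StanceMask.from_mask(
            np.concatenate([np.ones(50, bool), np.zeros(n - 50, bool)])
        )
        with pytest.warns(UserWarning):
            integrate_position_zvu(acc, mask, 100.0)


@pytest.fixture(scope="module")
def segmented(default_truth, ideal_sequences):
    seq = ideal_sequences["foot_L"]
    mask = detect_stance(seq)
    lin = remove_gravity(seq.acc, default_truth.segments["foot_L"].quat)
    _, pos = integrate_position_zvu(lin, mask, 100.0)
    return segment_strides(mask, pos, 100.0)


class TestSegmentStrides:

    def test_ten_simulated_strides_give_nine_records(self, segmented):
        assert len(segmented) == 9

    def test_parameters_match_truth(self, segmented):
        for s in segmented:
            assert abs(s.length - 1.21) < 0.02
            assert abs(s.cycle - 1.32) <= 0.01 + 1e-9
            assert abs(s.clearance_max - 0.22) < 0.01

    def test_cycle_is_stance_plus_swing(self, segmented):
        for s in segmented:
            assert s.cycle == pytest.approx(s.stance_time + s.swing_time, abs=1e-12)
            assert s.speed == pytest.approx(s.length / s.cycle, rel=1e-12)

    def test_too_few_intervals_warns(self):
        mask = StanceMask.from_mask(np.zeros(100, dtype=bool))
        with pytest.warns(UserWarning):
            assert segment_strides(mask, np.zeros((100, 3)), 100.0) == []


class TestSegmentAnglesOps:
    def test_initial_angle_vertical(self):
        assert initial_segment_angle(np.array([0.0, 0.0, GRAVITY])) == pytest.approx(0.0)

    def test_initial_angle_ten_degrees(self):
        a = GRAVITY * np.array([np.sin(np.radians(10)), 0.0, np.cos(np.radians(10))])
        assert np.degrees(initial_segment_angle(a)) == pytest.approx(10.0, abs=1e-6)

    def test_initial_angle_noisy_average(self, rng):
        a = GRAVITY * np.array([np.sin(0.2), 0.0, np.cos(0.2)])
        samples = a + rng.normal(0, 0.02, (100, 3))
        got = initial_segment_angle(samples)
        assert abs(np.degrees(got) - np.degrees(0.2)) < 0.2

    def test_initial_angle_rejects_dynamic(self):
        with pytest.raises(InvalidInputError):
            initial_segment_angle(np.array([5.0, 0.0, 5.0]))

    @staticmethod
    def _const_rate_pair(rate_diff_deg_s, duration=2.0, fs=100.0):
        """Thigh/shank pair whose inclination-rate difference is constant."""
        n = int(duration * fs) + 1
        t = np.arange(n) / fs
        acc = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        w = np.radians(rate_diff_deg_s)
        thigh = ImuSequence(t=t, acc=acc, gyro=np.tile([0.0, -w, 0.0], (n, 1)), fs=fs)
        shank = ImuSequence(t=t, acc=acc, gyro=np.zeros((n, 3)), fs=fs)
        return thigh, shank

    def test_knee_equal_rates_constant(self):
        thigh, shank = self._const_rate_pair(0.0)
        init = SegmentAngles(theta_thigh0=np.radians(4.0), theta_shank0=np.radians(-3.2))
        theta = knee_angle(thigh, shank, init)
        assert np.allclose(np.degrees(theta), 7.2, atol=1e-9)

    def test_knee_ramp_arithmetic(self):
        """10 deg/s for 2 s starting from 5 deg ends at 25 deg."""
        thigh, shank = self._const_rate_pair(10.0)
        init = SegmentAngles(theta_thigh0=np.radians(5.0), theta_shank0=0.0)
        theta = knee_angle(thigh, shank, init)
        assert np.degrees(theta[-1]) == pytest.approx(25.0, abs=1e-6)

    def test_ankle_plantarflexion_negative(self):
        """A foot pitching forward (toes down) drives the ankle negative."""
        n, fs = 201, 100.0
        t = np.arange(n) / fs
        acc = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        foot = ImuSequence(t=t, acc=acc, gyro=np.tile([0.0, -0.2, 0.0], (n, 1)), fs=fs)
        shank = ImuSequence(t=t, acc=acc, gyro=np.zeros((n, 3)), fs=fs)
        theta = ankle_angle(foot, shank, SegmentAngles())
        assert theta[-1] < -0.01

    def test_simulator_joint_recovery(self, default_truth, ideal_sequences):
        """Noiseless knee and ankle profiles recovered within 2 deg RMS."""
        thigh = ideal_sequences["thigh_L"]
        shank = ideal_sequences["shank_L"]
        foot = ideal_sequences["foot_L"]
        init = SegmentAngles(
            theta_thigh0=initial_segment_angle(thigh.acc[:100]),
            theta_shank0=initial_segment_angle(shank.acc[:100]),
            theta_foot0=initial_segment_angle(foot.acc[:100]),
        )
        knee = knee_angle(thigh, shank, init)
        ankle = ankle_angle(foot, shank, init)
        knee_rms = np.sqrt(np.mean(np.degrees(knee - default_truth.knee["L"]) ** 2))
        ankle_rms = np.sqrt(np.mean(np.degrees(ankle - default_truth.ankle["L"]) ** 2))
        assert knee_rms < 2.0
        assert ankle_rms < 2.0

    def test_alignment_failure(self):
        thigh, shank = self._const_rate_pair(0.0)
        shifted = ImuSequence(
            t=shank.t + 0.05, acc=shank.acc, gyro=shank.gyro, fs=shank.fs
        )
        with pytest.raises(InvalidInputError):
            knee_angle(thigh, shifted, SegmentAngles())


class TestRomAndParameters:
    def test_rom_constant_zero(self):
        assert knee_rom([np.full(50, 0.3)])[0] == pytest.approx(0.0)

    def test_rom_span_and_offset_invariance(self):
        series = np.radians(np.linspace(7.2, 66.2, 100))
        assert knee_rom([series])[0] == pytest.approx(59.0, abs=1e-9)
        assert knee_rom([series + 1.0])[0] == pytest.approx(59.0, abs=1e-9)

    def test_identical_strides_zero_sd(self, default_truth, ideal_sequences):
        seq = ideal_sequences["foot_L"]
        mask = detect_stance(seq)
        lin = remove_gravity(seq.acc, default_truth.segments["foot_L"].quat)
        _, pos = integrate_position_zvu(lin, mask, 100.0)
        strides = segment_strides(mask, pos, 100.0)
        params = compute_gait_parameters(strides)
        for mean, sd in params.summary().values():
            assert sd < 0.01 * max(abs(mean), 1.0)

    def test_speed_from_length_and_cycle(self):
        """1.21 m strides at 1.32 s cycles walk at ~0.917 m/s."""
        truth = simulate_truth(GaitModelConfig())
        row = truth.strides.iloc[0]
        assert row.length / row.cycle == pytest.approx(0.9166, abs=1e-3)

    def test_summary_brute_force(self, rng):
        from imugait.gait import GaitParameters

        vals = rng.normal(1.2, 0.1, 9)
        params = GaitParameters(
            stride_length=vals,
            stride_speed=vals,
            stride_frequency=vals,
            walking_cycle=vals,
            stance_time=vals,
            swing_time=vals,
            clearance=vals,
        )
        mean, sd = params.summary()["stride_length"]
        assert mean == pytest.approx(float(np.mean(vals)))
        assert sd == pytest.approx(float(np.std(vals, ddof=1)))


class TestRegistration:
    def test_recovers_planted_yaw(self, rng):
        ref = np.cumsum(rng.normal(size=(500, 3)), axis=0)
        th = 0.123
        c, s = np.cos(th), np.sin(th)
        Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        est = ref @ Rz.T + np.array([1.0, -2.0, 0.5])
        aligned, got = register_trajectory(est, ref)
        assert got == pytest.approx(-th, abs=1e-9)
        assert np.allclose(aligned, ref, atol=1e-9)
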