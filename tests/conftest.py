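"""Shared fixtures: simulated sessions reused across test modules."""

import warnings

import numpy as np
import pytest

from imugait.calibration import calibrate_accelerometer, calibrate_magnetometer
from imugait.simulate import (
    GaitModelConfig,
    SensorErrorModel,
    figure_eight_sweep,
    simulate_truth,
    static_orientation_cloud,
    synthesize_imu,
)


@pytest.fixture(scope="session")
def default_truth():
    """Ground-truth kinematics of the default 10-stride walking session."""
    return simulate_truth(GaitModelConfig())


@pytest.fixture(scope="session")
def ideal_sequences(default_truth):
    """Noiseless, distortion-free sensor streams of the default session."""
    return synthesize_imu(default_truth, SensorErrorModel.ideal())


@pytest.fixture(scope="session")
def noisy_error_model():
    return SensorErrorModel(seed=3)


@pytest.fixture(scope="session")
def noisy_sequences(default_truth, noisy_error_model):
    return synthesize_imu(default_truth, noisy_error_model)


@pytest.fixture(scope="session")
def noisy_calibrations(noisy_error_model):
    """Accelerometer + magnetometer calibrations fitted from simulated protocols."""
    accel = calibrate_accelerometer(static_orientation_cloud(noisy_error_model))
    mag = calibrate_magnetometer(figure_eight_sweep(noisy_error_model))
    return accel, mag


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
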