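"""Drift-corrected attitude estimation by a PI complementary filter.

Gyroscope integration tracks fast rotation but drifts; gravity (and
optionally the magnetic field) provide drift-free but noisy/slow references.
Each sample, the filter

1. predicts the sensor-frame direction of each global reference vector from
   the current attitude,
2. forms an error as the cross product of the (normalised) measurement with
   that prediction — zero when aligned, magnitude sin(misalignment),
3. feeds the error back onto the measured angular rate through a
   proportional-integral law ``ω' = ω + kp·e + ki·∫e dt`` (the integral term
   absorbs constant gyro bias), and
4. propagates the quaternion with the corrected rate.

The gravity correction is gated off whenever the specific-force magnitude
departs from g by more than 10%, so swing-phase linear acceleration cannot
corrupt the tilt estimate.  The magnetic reference is projected to the
(horizontal, vertical) plane form before comparison, making it a pure
heading correction that cannot disturb tilt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, GapError, InvalidInputError
from .quaternion import (
    quat_conjugate,
    quat_from_euler,
    quat_normalize,
    quat_propagate,
    rotate_vector,
)
from .sequence import GRAVITY, ImuSequence

__all__ = [
    "FusionConfig",
    "FusionState",
    "gravity_error",
    "magnetic_error",
    "pi_correct",
    "fuse_sequence",
    "initial_orientation",
]

_GLOBAL_UP = np.array([0.0, 0.0, 1.0])


@dataclass
class FusionConfig:
    """Gains of the PI complementary filter.

    kp : proportional gain (1/s when the unit error vector is read as an
        angle); larger = faster convergence to the references.
    ki : integral gain (1/s²); absorbs constant gyro bias.
    tau : integration step of the integral accumulator, s; None means the
        sampling interval.
    use_mag : apply the magnetic heading correction when a magnetometer
        channel is present.
    accel_gate : relative specific-force deviation |‖a‖-g|/g beyond which
        the gravity correction is skipped.
    gyro_gate : angular-rate norm (rad/s) beyond which the gravity
        correction is skipped; rotation is the direct observable of motion,
        so this rejects swing samples whose specific-force norm happens to
        pass the accelerometer gate while pointing away from gravity.
    gate_confirm : half-width (samples) of the centred window over which
        both gates must hold before the gravity correction is trusted.
        Movement onset/offset always leaves one or two samples whose
        specific force still looks gravity-like while already pointing off
        vertical; requiring confirmed quiescence on both sides excludes
        them (processing is offline, so the non-causal look-ahead is free).
    """

    kp: float = 2.0
    ki: float = 0.2
    tau: Optional[float] = None
    use_mag: bool = True
    accel_gate: float = 0.05
    gyro_gate: float = 0.15
    gate_confirm: int = 4
    #: anti-windup bound on the integral accumulator, rad/s; large enough to
    #: absorb any plausible residual gyro bias, small enough that transient
    #: wind-up during initial convergence decays quickly
    integral_limit: float = 0.02

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0:
            raise InvalidInputError("gains must be non-negative")
        if self.tau is not None and self.tau <= 0:
            raise InvalidInputError("tau must be positive")


@dataclass
class FusionState:
    """Running filter state: attitude, integral-error accumulator, time."""

    q: np.ndarray
    integral_error: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t: float = 0.0


def gravity_error(a_meas: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Cross product of the normalised measured specific force with the
    predicted sensor-frame gravity direction."""
    a_meas = np.asarray(a_meas, dtype=float)
    norm = np.linalg.norm(a_meas)
    if norm == 0.0:
        raise DegenerateInputError("zero-norm accelerometer sample")
    c = rotate_vector(quat_conjugate(q), _GLOBAL_UP)
    return np.cross(a_meas / norm, c)


def magnetic_error(
    m_meas: np.ndarray, q: np.ndarray, b_ref: Optional[np.ndarray] = None
) -> np.ndarray:
    """Heading-only magnetic correction vector.

    When ``b_ref`` (a unit global-frame reference field direction, e.g.
    the one observed during the initial standing stretch) is given, the
    predicted sensor-frame field is its conjugate rotation.  Otherwise the
    reference is rebuilt from the measurement itself:
    the measured (calibrated) field is rotated to the global frame and
    collapsed to the canonical form ``(sqrt(bx²+by²), 0, bz)``; the error is
    the cross product of the normalised measurement with that reference
    rotated back to the sensor frame, projected onto the predicted vertical
    axis.  The projection makes the correction heading-only by
    construction: without it, a heading error δ on a dipped field produces
    a spurious tilt component of order δ times the vertical field fraction,
    which corrupts pitch whenever gravity aiding is gated off.  A
    near-vertical field leaves heading unobservable: zero is returned with
    a warning.
    """
    m_meas = np.asarray(m_meas, dtype=float)
    norm = np.linalg.norm(m_meas)
    if norm == 0.0:
        raise DegenerateInputError("zero-norm magnetometer sample")
    m_hat = m_meas / norm
    if b_ref is not None:
        b = np.asarray(b_ref, dtype=float)
        horiz = float(np.hypot(b[0], b[1]))
    else:
        h = rotate_vector(q, m_hat)
        horiz = float(np.hypot(h[0], h[1]))
        b = np.array([horiz, 0.0, h[2]]) if horiz >= 1e-6 else h
    if horiz < 1e-6:
        warnings.warn("magnetic field is vertical; heading unobservable, no correction applied")
        return np.zeros(3)
    v = rotate_vector(quat_conjugate(q), b)
    e = np.cross(m_hat, v)
    up = rotate_vector(quat_conjugate(q), _GLOBAL_UP)
    # normalise to unit heading gain: the raw vertical component of the
    # cross product scales with the squared horizontal field fraction,
    # which would leave yaw only weakly coupled on a steeply dipped field
    return (float(e @ up) / max(horiz * horiz, 1e-6)) * up


def pi_correct(
    omega: np.ndarray, err: np.ndarray, state: FusionState, cfg: FusionConfig
) -> np.ndarray:
    """Apply the PI feedback law; mutates the state's integral accumulator."""
    omega = np.asarray(omega, dtype=float)
    err = np.asarray(err, dtype=float)
    tau = cfg.tau if cfg.tau is not None else 0.01
    if cfg.ki > 0:
        acc = state.integral_error + err * tau
        norm = float(np.linalg.norm(acc))
        if cfg.integral_limit and norm > cfg.integral_limit:
            acc = acc * (cfg.integral_limit / norm)
        state.integral_error = acc
    return omega + cfg.kp * err + cfg.ki * state.integral_error


def fuse_sequence(
    seq: ImuSequence,
    cfg: FusionConfig | None = None,
    q0: np.ndarray | None = None,
    b_ref: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Run the complementary filter over a calibrated sequence.

    Parameters
    ----------
    seq : calibrated sensor stream.
    cfg : filter gains; defaults are suitable at 100 Hz.
    q0 : initial unit attitude; estimated from the first second of data
        (assumed quasi-static) when None.
    b_ref : optional unit global-frame magnetic reference direction.  When
        given, heading is corrected toward this fixed reference (anchoring
        it to the field observed at a known orientation makes the heading
        immune to residual calibration error there); when None the
        reference is rebuilt from each measurement by horizontal
        projection.

    Returns
    -------
    (n, 4) array of unit quaternions, one per sample; row 0 is ``q0``.

    Raises
    ------
    GapError when any timestamp gap exceeds 5 nominal sample periods.
    """
    cfg = cfg or FusionConfig()
    n = len(seq)
    if n < 2:
        raise InvalidInputError("need at least two samples to fuse")
    dts = np.diff(seq.t)
    gap_idx = np.flatnonzero(dts > 5.0 / seq.fs)
    if gap_idx.size:
        raise GapError(f"timestamp gaps > 5 sample periods after samples {gap_idx.tolist()}")
    if q0 is None:
        q0 = initial_orientation(seq, use_mag=cfg.use_mag and seq.mag is not None)
    state = FusionState(q=quat_normalize(q0), t=float(seq.t[0]))
    use_mag = cfg.use_mag and seq.mag is not None
    out = np.empty((n, 4))
    out[0] = state.q
    # quiescence gating, confirmed over a centred window
    a_norms = np.linalg.norm(seq.acc, axis=1)
    static_ok = (a_norms > 0) & (
        np.abs(a_norms - GRAVITY) / GRAVITY <= cfg.accel_gate
    ) & (np.linalg.norm(seq.gyro, axis=1) <= cfg.gyro_gate)
    if cfg.gate_confirm > 0:
        k = int(cfg.gate_confirm)
        win = np.lib.stride_tricks.sliding_window_view(
            np.pad(static_ok, k, constant_values=False), 2 * k + 1
        )
        static_ok = win.all(axis=-1)
    tau_cfg = cfg.tau
    for i in range(1, n):
        dt = float(dts[i - 1])
        if tau_cfg is None:
            cfg.tau = dt
        a = seq.acc[i - 1]
        err = np.zeros(3)
        if static_ok[i - 1]:
            err = err + gravity_error(a, state.q)
        if use_mag:
            err = err + magnetic_error(seq.mag[i - 1], state.q, b_ref=b_ref)
        # midpoint rate over [t_{i-1}, t_i]: avoids the half-sample attitude
        # lag a left-endpoint rule would leave at walking-scale rates
        omega = pi_correct(0.5 * (seq.gyro[i - 1] + seq.gyro[i]), err, state, cfg)
        state.q = quat_propagate(state.q, omega, dt)
        state.t = float(seq.t[i])
        out[i] = state.q
    cfg.tau = tau_cfg
    return out


def initial_orientation(
    seq: ImuSequence,
    n_static: Optional[int] = None,
    use_mag: bool = True,
    acc_mean: Optional[np.ndarray] = None,
    mag_mean: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Initial attitude from a quasi-static stretch at the start of a recording.

    Roll and pitch come from the mean accelerometer direction; yaw from the
    tilt-compensated mean magnetometer heading (zero without magnetometer).
    The yaw convention puts the horizontal magnetic field along global +x.
    ``acc_mean`` / ``mag_mean`` override the first-window averages with
    externally computed ones (e.g. over all stance samples of a foot
    sensor, which shares the standing orientation but averages far more
    noise away).
    """
    if n_static is None:
        n_static = max(3, int(round(seq.fs)))
    n_static = min(n_static, len(seq))
    a = acc_mean if acc_mean is not None else np.mean(seq.acc[:n_static], axis=0)
    a = np.asarray(a, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0.0:
        raise DegenerateInputError("zero mean specific force in the static window")
    a_hat = a / norm
    # sensor-frame gravity direction (-sin(theta), sin(phi) cos(theta), cos(phi) cos(theta))
    theta = float(-np.arcsin(np.clip(a_hat[0], -1.0, 1.0)))
    phi = float(np.arctan2(a_hat[1], a_hat[2]))
    psi = 0.0
    if use_mag and seq.mag is not None:
        m = mag_mean if mag_mean is not None else np.mean(seq.mag[:n_static], axis=0)
        m = np.asarray(m, dtype=float)
        if np.linalg.norm(m) > 0:
            q_rp = quat_from_euler(phi, theta, 0.0)
            h = rotate_vector(q_rp, m / np.linalg.norm(m))
            if np.hypot(h[0], h[1]) >= 1e-6:
                psi = float(np.arctan2(-h[1], h[0]))
    return quat_from_euler(phi, theta, psi)
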