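"""Unit-quaternion algebra for attitude representation.

Conventions (used consistently across the package):

* Hamilton product, scalar-first storage ``q = (q0, q1, q2, q3)``,
  right-handed axes.
* A quaternion maps the *sensor* frame to the *global* frame:
  ``v_global = R(q) v_sensor``, so the predicted sensor-frame direction of a
  global reference vector (gravity, magnetic north) is obtained with the
  conjugate rotation.
* Euler angles are intrinsic z-y-x (yaw ``psi``, pitch ``theta``, roll
  ``phi``), pitch restricted to [-pi/2, pi/2].

All public operations return unit quaternions (renormalised to within 1e-9).
Quaternions are plain ``numpy`` arrays of shape ``(4,)``; trajectories are
``(n, 4)`` arrays.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "EulerAngles",
    "quat_identity",
    "quat_normalize",
    "quat_conjugate",
    "quat_multiply",
    "quat_from_axis_angle",
    "quat_from_euler",
    "quat_to_matrix",
    "quat_angle",
    "quat_propagate",
    "quat_to_euler",
    "quat_slerp",
    "quat_nlerp",
    "rotate_vector",
    "rotate_vectors",
]


class EulerAngles(NamedTuple):
    """Roll / pitch / yaw in radians (intrinsic z-y-x decomposition)."""

    phi: float
    theta: float
    psi: float


def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0.0 or not np.isfinite(n):
        raise DegenerateInputError("cannot normalise a zero or non-finite quaternion")
    return q / n


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product ``p ⊗ q`` (apply q first when composing rotations)."""
    p0, p1, p2, p3 = p
    q0, q1, q2, q3 = q
    return np.array(
        [
            p0 * q0 - p1 * q1 - p2 * q2 - p3 * q3,
            p0 * q1 + p1 * q0 + p2 * q3 - p3 * q2,
            p0 * q2 - p1 * q3 + p2 * q0 + p3 * q1,
            p0 * q3 + p1 * q2 - p2 * q1 + p3 * q0,
        ]
    )


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise DegenerateInputError("rotation axis must be non-zero")
    half = 0.5 * float(angle)
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def quat_from_euler(phi: float, theta: float, psi: float) -> np.ndarray:
    """Unit quaternion of the intrinsic z-y-x rotation R = Rz(psi) Ry(theta) Rx(phi)."""
    qz = quat_from_axis_angle([0, 0, 1], psi)
    qy = quat_from_axis_angle([0, 1, 0], theta)
    qx = quat_from_axis_angle([1, 0, 0], phi)
    return quat_normalize(quat_multiply(quat_multiply(qz, qy), qx))


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix R such that v_global = R v_sensor."""
    q0, q1, q2, q3 = quat_normalize(q)
    return np.array(
        [
            [
                q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                2 * (q1 * q2 - q0 * q3),
                2 * (q1 * q3 + q0 * q2),
            ],
            [
                2 * (q1 * q2 + q0 * q3),
                q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3,
                2 * (q2 * q3 - q0 * q1),
            ],
            [
                2 * (q1 * q3 - q0 * q2),
                2 * (q2 * q3 + q0 * q1),
                q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3,
            ],
        ]
    )


def quat_angle(p: np.ndarray, q: np.ndarray) -> float:
    """Geodesic rotation angle between two unit quaternions (sign-agnostic)."""
    d = abs(float(np.dot(quat_normalize(p), quat_normalize(q))))
    return 2.0 * np.arccos(min(d, 1.0))


def quat_propagate(q: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """Advance the attitude by one sample of body-frame angular rate.

    Integrates the quaternion kinematic differential equation
    ``q̇ = ½ q ⊗ (0, ω)`` (equivalently the 4x4 skew-symmetric rate-matrix
    form) with a single first-order step followed by renormalisation —
    accurate to ``O((‖ω‖ dt)³)`` per step, ample at 100 Hz rates.

    Parameters
    ----------
    q : unit quaternion, sensor→global.
    omega : body-frame angular velocity, rad/s.
    dt : time step, s (must be positive).
    """
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise InvalidInputError("angular rate contains non-finite values")
    if not (np.isfinite(dt) and dt > 0):
        raise InvalidInputError(f"dt must be positive and finite, got {dt!r}")
    w = np.concatenate([[0.0], omega])
    dq = 0.5 * quat_multiply(q, w)
    return quat_normalize(np.asarray(q, dtype=float) + dq * dt)


def quat_to_euler(q: np.ndarray) -> EulerAngles:
    """Roll, pitch, yaw of the sensor→global rotation.

    The pitch arcsin argument is clamped to [-1, 1] so round-off at the
    gimbal singularity cannot raise.
    """
    q0, q1, q2, q3 = quat_normalize(q)
    phi = np.arctan2(2 * (q2 * q3 + q0 * q1), q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3)
    s = np.clip(-2 * (q1 * q3 - q0 * q2), -1.0, 1.0)
    theta = np.arcsin(s)
    psi = np.arctan2(2 * (q1 * q2 + q0 * q3), q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3)
    return EulerAngles(float(phi), float(theta), float(psi))


_NLERP_FALLBACK_ANGLE = 1e-6  # rad; below this sin(theta) underflows in slerp


def _check_t(t: float) -> float:
    t = float(t)
    if not (0.0 <= t <= 1.0):
        raise InvalidInputError(f"interpolation fraction must lie in [0, 1], got {t}")
    return t


def quat_nlerp(qm: np.ndarray, qn: np.ndarray, t: float) -> np.ndarray:
    """Normalised linear interpolation ``(qm + t (qn - qm)) / ‖·‖``.

    Raises :class:`DegenerateInputError` when the linear blend passes through
    the origin (antipodal endpoints at t = 0.5).
    """
    t = _check_t(t)
    qm = quat_normalize(qm)
    qn = quat_normalize(qn)
    blend = qm + (qn - qm) * t
    n = np.linalg.norm(blend)
    if n < 1e-12:
        raise DegenerateInputError("nlerp through the origin: endpoints are antipodal")
    return blend / n


def quat_slerp(qm: np.ndarray, qn: np.ndarray, t: float) -> np.ndarray:
    """Spherical linear interpolation with shortest-path sign handling.

    The angle between ``qm`` and the result is linear in ``t``.  For nearly
    parallel endpoints (< 1e-6 rad) the numerically safer nlerp is used; the
    two agree to far better than the switchover scale there.
    """
    t = _check_t(t)
    qm = quat_normalize(qm)
    qn = quat_normalize(qn)
    dot = float(np.dot(qm, qn))
    if dot < 0.0:  # take the short arc
        qn = -qn
        dot = -dot
    dot = min(dot, 1.0)
    theta = np.arccos(dot)
    if theta < _NLERP_FALLBACK_ANGLE:
        return quat_nlerp(qm, qn, t)
    s = np.sin(theta)
    out = (np.sin((1.0 - t) * theta) / s) * qm + (np.sin(t * theta) / s) * qn
    return quat_normalize(out)


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate a 3-vector from the sensor frame to the global frame."""
    return quat_to_matrix(q) @ np.asarray(v, dtype=float)


def rotate_vectors(quats: np.ndarray, vecs: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Vectorised frame transformation of per-sample 3-vectors.

    Parameters
    ----------
    quats : (n, 4) unit quaternions (sensor→global).
    vecs : (n, 3) vectors, or (3,) broadcast to all samples.
    inverse : rotate global→sensor instead.
    """
    quats = np.atleast_2d(np.asarray(quats, dtype=float))
    vecs = np.asarray(vecs, dtype=float)
    if vecs.ndim == 1:
        vecs = np.broadcast_to(vecs, (quats.shape[0], 3))
    q0 = quats[:, 0:1]
    u = -quats[:, 1:] if inverse else quats[:, 1:]  # conjugation negates the vector part
    # v' = v + 2 q0 (u x v) + 2 u x (u x v)
    uxv = np.cross(u, vecs)
    return vecs + 2.0 * q0 * uxv + 2.0 * np.cross(u, uxv)
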