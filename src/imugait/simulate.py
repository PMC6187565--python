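"""Parametric lower-limb gait simulator with ground truth.

Generates smooth, twice-differentiable foot / shank / thigh trajectories
that realise a configured stride length, foot clearance, cycle duration,
stance fraction and knee-flexion profile *exactly*, then passes them
through a forward sensor-error model (triad non-orthogonality, additive
bias, white noise, hard/soft-iron magnetic distortion) to produce raw IMU
streams.  Every recovery test in the repository closes the loop against the
truth tables returned here.

Kinematic model
---------------
Global frame: x forward, y left, z up; gravity (0, 0, -9.81) m/s².  A
session is quiet standing, ``n_strides`` gait cycles, quiet standing.  Each
cycle is stance (foot stationary on the ground) followed by swing, during
which the foot advances one stride length along a quintic-smoothstep
profile and rises along a ``sin²`` clearance bump, with a smooth sagittal
pitch oscillation.  The right foot runs half a cycle out of phase.  Thigh
and shank angles are built so the knee flexion (thigh minus shank
inclination) is at its standing value throughout stance and follows a
``sin²`` bump peaking mid-swing; thigh/shank sensors translate with the hip
(sensor-at-segment-axis approximation) while rotating with their segment.

Default parameter scales follow healthy-adult walking: 1.21 m strides,
1.32 s cycle, 65% stance, 0.22 m clearance, knee flexion from 7.2° to
66.2°.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .calibration import NonOrthoAngles, nonortho_matrix
from .errors import InvalidInputError
from .quaternion import rotate_vectors
from .sequence import GRAVITY, ImuSequence
from .stance import StanceMask

__all__ = [
    "GaitModelConfig",
    "SensorErrorModel",
    "SegmentTruth",
    "GaitTruth",
    "simulate_truth",
    "synthesize_imu",
    "static_orientation_cloud",
    "figure_eight_sweep",
    "MAGNETIC_FIELD",
]

#: global reference magnetic field (arbitrary units), +x horizontal with dip
MAGNETIC_FIELD = np.array([22.0, 0.0, -40.0])

_SIDES = ("L", "R")
_PHASE_OFFSET = {"L": 0.0, "R": 0.5}


@dataclass
class GaitModelConfig:
    """Gait-pattern parameters; defaults are healthy-adult scale."""

    n_strides: int = 10
    cycle_s: float = 1.32
    stance_fraction: float = 0.65
    stride_length_m: float = 1.21
    clearance_m: float = 0.22
    knee_peak_deg: float = 66.2
    knee_min_deg: float = 7.2
    thigh_lean_deg: float = 4.0
    thigh_sweep_deg: float = 30.0
    foot_pitch_deg: float = 15.0
    fs: float = 100.0
    static_s: float = 2.0
    rest_s: float = 1.0
    #: per-side (left, right) multiplicative scales
    length_scale: Tuple[float, float] = (1.0, 1.0)
    clearance_scale: Tuple[float, float] = (1.0, 1.0)
    rom_scale: Tuple[float, float] = (1.0, 1.0)
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0.0 < self.stance_fraction < 1.0):
            raise InvalidInputError("stance_fraction must be in (0, 1)")
        for name in ("cycle_s", "stride_length_m", "clearance_m", "fs"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.n_strides < 1:
            raise InvalidInputError("need at least one stride")
        if self.clearance_m * max(self.clearance_scale) > 0.8:
            raise InvalidInputError("clearance exceeds plausible leg length")
        if self.knee_peak_deg <= self.knee_min_deg:
            raise InvalidInputError("knee peak must exceed the standing knee angle")

    def side_params(self, side: str) -> Tuple[float, float, float]:
        """(stride length, clearance, knee-ROM amplitude in rad) for a side."""
        i = _SIDES.index(side)
        rom = np.radians(self.knee_peak_deg - self.knee_min_deg) * self.rom_scale[i]
        return (
            self.stride_length_m * self.length_scale[i],
            self.clearance_m * self.clearance_scale[i],
            rom,
        )


@dataclass
class SensorErrorModel:
    """Forward sensor-error model: white noise, constant bias, distortions.

    Noise/bias scales follow a MEMS wearable-grade specification
    (accelerometer 0.02 m/s², gyroscope ~1 deg/s noise with 0.01 rad/s bias,
    magnetometer noise small against a ~46-unit field); distortion defaults
    inject sub-degree triad misalignment and a clearly visible hard/soft-iron
    pair so calibration is always exercised.
    """

    accel_noise_sd: float = 0.02
    gyro_noise_sd: float = 0.0175
    gyro_bias: float = 0.01
    accel_bias: float = 0.02
    mag_noise_sd: float = 0.2
    nonortho: NonOrthoAngles = dc_field(
        default_factory=lambda: NonOrthoAngles(*np.radians([0.5, 0.3, 0.8]))
    )
    hard_iron: np.ndarray = dc_field(default_factory=lambda: np.array([10.0, -5.0, 3.0]))
    soft_iron: np.ndarray = dc_field(default_factory=lambda: np.diag([1.1, 0.9, 1.0]))
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("accel_noise_sd", "gyro_noise_sd", "mag_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        self.hard_iron = np.asarray(self.hard_iron, dtype=float)
        self.soft_iron = np.asarray(self.soft_iron, dtype=float)

    @classmethod
    def ideal(cls, seed: int = 42) -> "SensorErrorModel":
        """Noiseless, distortion-free sensors (identity error model)."""
        return cls(
            accel_noise_sd=0.0,
            gyro_noise_sd=0.0,
            gyro_bias=0.0,
            accel_bias=0.0,
            mag_noise_sd=0.0,
            nonortho=NonOrthoAngles(0.0, 0.0, 0.0),
            hard_iron=np.zeros(3),
            soft_iron=np.eye(3),
            seed=seed,
        )

    def bias_vectors(self, segment: str) -> Tuple[np.ndarray, np.ndarray]:
        """Deterministic per-segment (accel, gyro) bias vectors.

        Drawn from a dedicated stream keyed on (seed, segment) so a static
        calibration cloud and a walking session generated from the same
        error model share the same biases.
        """
        tag = sum(ord(c) for c in segment)
        rng = np.random.default_rng([self.seed, tag])
        ab = rng.uniform(-1.0, 1.0, 3) * self.accel_bias
        gb = rng.uniform(-1.0, 1.0, 3) * self.gyro_bias
        return ab, gb


# ---------------------------------------------------------------------------
# smooth primitives (value and derivatives in the unit-interval variable)

def _smoothstep(s: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quintic smoothstep: C² with zero first/second derivatives at 0 and 1."""
    h = s**3 * (10.0 - 15.0 * s + 6.0 * s * s)
    dh = 30.0 * s**2 * (s - 1.0) ** 2
    d2h = 60.0 * s * (2.0 * s - 1.0) * (s - 1.0)
    return h, dh, d2h


def _smoothstep7(s: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """7th-order smoothstep: first three derivatives vanish at 0 and 1.

    Used for the swing advance so the sampled acceleration is C¹ with flat
    ends — trapezoidal re-integration of the synthesized accelerometer then
    reproduces the trajectory without a per-stride bias.
    """
    h = s**4 * (35.0 - 84.0 * s + 70.0 * s * s - 20.0 * s**3)
    dh = s**3 * (140.0 - 420.0 * s + 420.0 * s * s - 140.0 * s**3)
    d2h = s * s * (420.0 - 1680.0 * s + 2100.0 * s * s - 840.0 * s**3)
    return h, dh, d2h


def _bump(s: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """sin² bump: 0→1→0 over [0,1] with zero end slopes."""
    b = np.sin(np.pi * s) ** 2
    db = np.pi * np.sin(2.0 * np.pi * s)
    d2b = 2.0 * np.pi**2 * np.cos(2.0 * np.pi * s)
    return b, db, d2b


def _bump4(s: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """sin⁴ bump: like sin² but with zero end curvature (C¹ acceleration)."""
    sp, cp = np.sin(np.pi * s), np.cos(np.pi * s)
    b = sp**4
    db = 4.0 * np.pi * sp**3 * cp
    d2b = 4.0 * np.pi**2 * sp * sp * (3.0 * cp * cp - sp * sp)
    return b, db, d2b


def _pitch_profile(s: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Antisymmetric swing pitch sin(2πs)·sin²(πs): plantar- then dorsiflexion."""
    p = np.sin(2.0 * np.pi * s) * np.sin(np.pi * s) ** 2
    dp = (
        2.0 * np.pi * np.cos(2.0 * np.pi * s) * np.sin(np.pi * s) ** 2
        + np.pi * np.sin(2.0 * np.pi * s) ** 2
    )
    return p, dp


def _quat_about_y(theta: np.ndarray) -> np.ndarray:
    """(n,4) unit quaternions for rotation about global y by −theta each.

    With the sensor→global convention a segment leaning forward by
    inclination θ has ``q = (cos(θ/2), 0, −sin(θ/2), 0)`` so its static
    accelerometer reads ``(g sinθ, 0, g cosθ)``.
    """
    half = -0.5 * np.asarray(theta, dtype=float)
    q = np.zeros(theta.shape + (4,))
    q[..., 0] = np.cos(half)
    q[..., 2] = np.sin(half)
    return q


@dataclass
class SegmentTruth:
    """Ground-truth kinematics of one sensor site."""

    pos: np.ndarray
    vel: np.ndarray
    acc: np.ndarray
    quat: np.ndarray
    omega: np.ndarray
    incline: np.ndarray  # sagittal inclination series, rad


@dataclass
class GaitTruth:
    """Everything the pipeline is later asked to recover."""

    cfg: GaitModelConfig
    t: np.ndarray
    segments: Dict[str, SegmentTruth]
    stance: Dict[str, np.ndarray]  # side -> boolean truth stance mask
    knee: Dict[str, np.ndarray]  # side -> knee flexion series, rad
    ankle: Dict[str, np.ndarray]  # side -> ankle angle series, rad
    strides: pd.DataFrame

    def stance_mask(self, side: str) -> StanceMask:
        return StanceMask.from_mask(self.stance[side])


def _foot_kinematics(cfg: GaitModelConfig, t: np.ndarray, side: str):
    """Closed-form foot trajectory, pitch and their derivatives for one side."""
    L, C, _ = cfg.side_params(side)
    c = cfg.cycle_s
    t0 = cfg.static_s
    t_end = t0 + cfg.n_strides * c
    T_sw = c * (1.0 - cfg.stance_fraction)
    offset = _PHASE_OFFSET[side]
    k_first = int(np.floor(-offset)) if offset > 0 else 0

    ph = (t - t0) / c - offset
    walking = (t >= t0) & (t < t_end)
    k = np.floor(ph).astype(int)
    frac = ph - k
    swing = walking & (frac >= cfg.stance_fraction)
    s = np.where(swing, (frac - cfg.stance_fraction) / (1.0 - cfg.stance_fraction), 0.0)
    swings_done = np.where(walking, k - k_first, 0)
    total_swings = cfg.n_strides
    swings_done = np.where(t >= t_end, total_swings, swings_done)

    h, dh, d2h = _smoothstep7(s)
    b, db, d2b = _bump4(s)
    p, dp = _pitch_profile(s)

    x = L * (swings_done + np.where(swing, h, 0.0))
    vx = np.where(swing, L * dh / T_sw, 0.0)
    ax = np.where(swing, L * d2h / T_sw**2, 0.0)
    z = np.where(swing, C * b, 0.0)
    vz = np.where(swing, C * db / T_sw, 0.0)
    az = np.where(swing, C * d2b / T_sw**2, 0.0)

    A_f = np.radians(cfg.foot_pitch_deg)
    theta = np.where(swing, A_f * p, 0.0)
    dtheta = np.where(swing, A_f * dp / T_sw, 0.0)

    y = 0.1 if side == "L" else -0.1
    n = t.shape[0]
    pos = np.column_stack([x, np.full(n, y), z])
    vel = np.column_stack([vx, np.zeros(n), vz])
    acc = np.column_stack([ax, np.zeros(n), az])
    stance_mask = ~swing
    return pos, vel, acc, theta, dtheta, stance_mask, swing, s


def _envelope(cfg: GaitModelConfig, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Walk-amplitude envelope: smoothstep in over the first cycle, out over the last."""
    t0 = cfg.static_s
    t_end = t0 + cfg.n_strides * cfg.cycle_s
    c = cfg.cycle_s
    su = np.clip((t - t0) / c, 0.0, 1.0)
    sd = np.clip((t_end - t) / c, 0.0, 1.0)
    hu, dhu, _ = _smoothstep(su)
    hd, dhd, _ = _smoothstep(sd)
    inside = (t >= t0) & (t < t_end)
    env = np.where(inside, hu * hd, 0.0)
    denv = np.where(inside, (dhu / c) * hd - hu * (dhd / c), 0.0)
    return env, denv


def simulate_truth(cfg: Optional[GaitModelConfig] = None) -> GaitTruth:
    """Generate ground-truth kinematics for all six sensor sites.

    Per-stride truth parameters equal the configured values exactly by
    construction.
    """
    cfg = cfg or GaitModelConfig()
    c = cfg.cycle_s
    t0 = cfg.static_s
    t_end = t0 + cfg.n_strides * c
    total = t_end + cfg.rest_s
    n = int(round(total * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs

    env, denv = _envelope(cfg, t)
    theta_T0 = np.radians(cfg.thigh_lean_deg)
    sweep = np.radians(cfg.thigh_sweep_deg)
    knee_min = np.radians(cfg.knee_min_deg)

    segments: Dict[str, SegmentTruth] = {}
    stance: Dict[str, np.ndarray] = {}
    knee: Dict[str, np.ndarray] = {}
    ankle: Dict[str, np.ndarray] = {}
    rows = []
    foot_x = {}

    for side in _SIDES:
        L, C, rom_amp = cfg.side_params(side)
        pos, vel, acc, th_f, dth_f, st_mask, swing, s = _foot_kinematics(cfg, t, side)
        foot_x[side] = (pos, vel, acc)
        segments[f"foot_{side}"] = SegmentTruth(
            pos=pos,
            vel=vel,
            acc=acc,
            quat=_quat_about_y(th_f),
            omega=np.column_stack([np.zeros(n), -dth_f, np.zeros(n)]),
            incline=th_f,
        )
        stance[side] = st_mask

        # thigh/shank angle profiles tied to this side's phase
        offset = _PHASE_OFFSET[side]
        ph = (t - t0) / c - offset
        dev = 0.5 * (np.cos(2.0 * np.pi * ph) - 1.0)
        ddev = -np.pi * np.sin(2.0 * np.pi * ph) / c
        walking = (t >= t0) & (t < t_end)
        dev = np.where(walking, dev, 0.0)
        ddev = np.where(walking, ddev, 0.0)
        th_thigh = theta_T0 + sweep * dev * env
        dth_thigh = sweep * (ddev * env + dev * denv)

        T_sw = c * (1.0 - cfg.stance_fraction)
        kb, dkb, _ = _bump(s)
        th_knee = knee_min + rom_amp * np.where(swing, kb, 0.0)
        dth_knee = rom_amp * np.where(swing, dkb / T_sw, 0.0)
        th_shank = th_thigh - th_knee
        dth_shank = dth_thigh - dth_knee

        knee[side] = th_knee
        ankle[side] = th_shank - th_f

        # per-stride truth rows: ICs at this side's cycle starts
        n_ic = cfg.n_strides + 1 if side == "L" else cfg.n_strides
        ic_times = t0 + (np.arange(n_ic) + offset) * c
        for j in range(len(ic_times) - 1):
            rows.append(
                {
                    "side": side,
                    "ic": ic_times[j],
                    "fo": ic_times[j] + cfg.stance_fraction * c,
                    "cycle": c,
                    "stance_time": cfg.stance_fraction * c,
                    "swing_time": (1.0 - cfg.stance_fraction) * c,
                    "length": L,
                    "clearance": C,
                    "knee_rom": float(np.degrees(rom_amp)),
                }
            )

        for seg_name, th, dth, height in (
            (f"thigh_{side}", th_thigh, dth_thigh, 0.75),
            (f"shank_{side}", th_shank, dth_shank, 0.35),
        ):
            segments[seg_name] = SegmentTruth(
                pos=None,  # filled below (needs both feet for the hip)
                vel=None,
                acc=None,
                quat=_quat_about_y(th),
                omega=np.column_stack([np.zeros(n), -dth, np.zeros(n)]),
                incline=th,
            )
            segments[seg_name]._height = height  # type: ignore[attr-defined]

    # hip progression = mean of the feet; thigh/shank sensors translate with it
    hip_pos = 0.5 * (foot_x["L"][0] + foot_x["R"][0])
    hip_vel = 0.5 * (foot_x["L"][1] + foot_x["R"][1])
    hip_acc = 0.5 * (foot_x["L"][2] + foot_x["R"][2])
    for side in _SIDES:
        y = 0.1 if side == "L" else -0.1
        for seg_name in (f"thigh_{side}", f"shank_{side}"):
            seg = segments[seg_name]
            h = seg._height  # type: ignore[attr-defined]
            seg.pos = hip_pos * np.array([1.0, 0.0, 0.0]) + np.array([0.0, y, h])
            seg.vel = hip_vel * np.array([1.0, 0.0, 0.0])
            seg.acc = hip_acc * np.array([1.0, 0.0, 0.0])
            del seg._height  # type: ignore[attr-defined]

    strides = pd.DataFrame(rows).sort_values(["side", "ic"]).reset_index(drop=True)
    return GaitTruth(
        cfg=cfg, t=t, segments=segments, stance=stance, knee=knee, ankle=ankle, strides=strides
    )


def synthesize_imu(
    truth: GaitTruth, err: Optional[SensorErrorModel] = None
) -> Dict[str, ImuSequence]:
    """Pass ground-truth kinematics through the sensor-error model.

    Sensor-frame specific force is ``Rᵀ(a_lin + g ẑ)`` distorted by the
    non-orthogonality matrix plus bias and seeded white noise; the gyroscope
    adds bias and noise to the true body rates; the magnetometer applies the
    soft-iron matrix to the body-frame reference field and adds the
    hard-iron offset and noise.  Output is bit-reproducible for a fixed
    seed.
    """
    err = err or SensorErrorModel()
    E = nonortho_matrix(err.nonortho)
    g_vec = np.array([0.0, 0.0, GRAVITY])
    out: Dict[str, ImuSequence] = {}
    for name, seg in truth.segments.items():
        tag = sum(ord(c) for c in name)
        rng = np.random.default_rng([err.seed, 7919, tag])
        accel_bias, gyro_bias = err.bias_vectors(name)
        f_body = rotate_vectors(seg.quat, seg.acc + g_vec, inverse=True)
        n = f_body.shape[0]
        acc_raw = f_body @ E.T + accel_bias + rng.normal(0.0, err.accel_noise_sd, (n, 3))
        gyro_raw = seg.omega + gyro_bias + rng.normal(0.0, err.gyro_noise_sd, (n, 3))
        m_body = rotate_vectors(seg.quat, MAGNETIC_FIELD, inverse=True)
        mag_raw = m_body @ err.soft_iron.T + err.hard_iron
        mag_raw = mag_raw + rng.normal(0.0, err.mag_noise_sd, (n, 3))
        out[name] = ImuSequence(
            t=truth.t, acc=acc_raw, gyro=gyro_raw, mag=mag_raw, fs=truth.cfg.fs, segment=name
        )
    return out


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit directions on the sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def static_orientation_cloud(
    err: Optional[SensorErrorModel] = None,
    n_orient: int = 64,
    samples_per_orientation: int = 300,
    segment: str = "foot_L",
) -> np.ndarray:
    """Multi-orientation static accelerometer samples for ellipsoid calibration.

    Gravity is presented along quasi-uniform sensor-frame directions
    (Fibonacci sphere) and passed through the same distortion model (and the
    same per-segment bias) as a walking session, so a fit on this cloud
    transfers to the session.  The defaults emulate a three-second dwell
    per orientation at 100 Hz — the noise averaging this buys is what sets
    the misalignment-angle accuracy, and through it the cross-axis
    acceleration leakage of the whole position pipeline.
    """
    err = err or SensorErrorModel()
    if n_orient < 20:
        raise InvalidInputError("need at least 20 orientations for a reliable fit")
    E = nonortho_matrix(err.nonortho)
    accel_bias, _ = err.bias_vectors(segment)
    rng = np.random.default_rng([err.seed, 104729])
    dirs = _fibonacci_directions(n_orient)
    f_true = np.repeat(dirs, samples_per_orientation, axis=0) * GRAVITY
    noise = rng.normal(0.0, err.accel_noise_sd, f_true.shape)
    return f_true @ E.T + accel_bias + noise


def figure_eight_sweep(
    err: Optional[SensorErrorModel] = None, n_samples: int = 12000
) -> np.ndarray:
    """Magnetometer samples from a figure-eight orientation sweep.

    The sensed field direction follows a space-filling Lissajous path
    (precessing figure-eight loops) covering well over a hemisphere,
    distorted by the hard/soft-iron model plus noise.  The default length
    emulates two minutes of sweeping at 100 Hz; hard/soft-iron residuals
    scale with the inverse square root of this.
    """
    err = err or SensorErrorModel()
    rng = np.random.default_rng([err.seed, 15485863])
    u = np.arange(n_samples) / n_samples
    az = 6.0 * np.pi * u  # three precessing figure-eight loops
    el = 1.5 * np.sin(14.0 * np.pi * u)
    dirs = np.column_stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
    m_true = dirs * np.linalg.norm(MAGNETIC_FIELD)
    raw = m_true @ err.soft_iron.T + err.hard_iron
    return raw + rng.normal(0.0, err.mag_noise_sd, raw.shape)
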