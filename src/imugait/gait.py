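"""Spatio-temporal gait analysis from calibrated, attitude-resolved streams.

The position chain is classic zero-velocity-aided strapdown dead reckoning:
rotate the sensor-frame specific force to the global frame with the fused
attitude, subtract gravity, integrate twice — and, because the foot is
stationary during every stance phase, clamp velocity to zero there and
redistribute the residual velocity observed at each stance onset linearly
backward over the preceding swing.  A constant acceleration error over a
swing is cancelled *exactly* by that linear de-drift, which is what bounds
per-stride error.

Strides run from one initial contact (IC, stance-interval start) to the
next IC of the same foot.  Joint angles use the gyroscope-difference
integral between adjacent segments, anchored by accelerometer-derived
static inclinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InvalidInputError
from .quaternion import rotate_vectors
from .sequence import GRAVITY, ImuSequence
from .stance import StanceMask

__all__ = [
    "Stride",
    "SegmentAngles",
    "GaitParameters",
    "remove_gravity",
    "integrate_position_zvu",
    "segment_strides",
    "initial_segment_angle",
    "knee_angle",
    "ankle_angle",
    "knee_rom",
    "compute_gait_parameters",
    "register_trajectory",
    "gait_stance_intervals",
]

_GRAVITY_VEC = np.array([0.0, 0.0, GRAVITY])

#: stance intervals longer than this are standing rest, not gait stance
MAX_STANCE_S = 2.0


@dataclass
class Stride:
    """One gait cycle of a single foot (IC to the next IC)."""

    start_ic: float
    end_ic: float
    stance_time: float
    swing_time: float
    cycle: float
    length: float
    speed: float
    clearance_max: float
    start_idx: int
    end_idx: int
    positions: Optional[np.ndarray] = None


@dataclass
class SegmentAngles:
    """Initial segment inclinations (rad) and derived joint-angle series."""

    theta_thigh0: float = 0.0
    theta_shank0: float = 0.0
    theta_foot0: float = 0.0
    theta_knee: Optional[np.ndarray] = None
    theta_ankle: Optional[np.ndarray] = None


def remove_gravity(acc: np.ndarray, quats: np.ndarray) -> np.ndarray:
    """Global-frame linear acceleration: rotate specific force, subtract g·ẑ."""
    acc = np.asarray(acc, dtype=float)
    quats = np.asarray(quats, dtype=float)
    if acc.shape[0] != quats.shape[0]:
        raise InvalidInputError(
            f"length mismatch: {acc.shape[0]} accel samples vs {quats.shape[0]} quaternions"
        )
    return rotate_vectors(quats, acc) - _GRAVITY_VEC


def integrate_position_zvu(
    lin_acc: np.ndarray,
    mask: StanceMask,
    fs: float,
    apply_zvu: bool = True,
    margin: int = 3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Double-integrate linear acceleration with zero-velocity updates.

    Velocity is clamped to zero inside every stance interval; the residual
    velocity accumulated over each swing (the value the raw integral shows
    at the next stance onset) is removed by subtracting a linear ramp over
    the swing samples.  ``apply_zvu=False`` gives the uncorrected dead
    reckoning for comparison.

    ``margin`` erodes each stance interval by that many samples on both
    sides before clamping (when the interval is long enough), so a
    detection boundary that is off by a sample or two cannot clamp — and
    the de-drift cannot misattribute — genuine slow foot motion at the
    stance edges.

    Returns ``(velocity, position)``, both (n, 3) in the global frame, m/s
    and m, starting from rest at the origin.
    """
    a = np.asarray(lin_acc, dtype=float)
    n = a.shape[0]
    if mask.mask.shape[0] != n:
        raise InvalidInputError("stance mask and acceleration lengths differ")
    dt = 1.0 / fs
    v_raw = cumulative_trapezoid(a, dx=dt, axis=0, initial=0.0)
    v = v_raw
    if apply_zvu:
        intervals = mask.intervals
        if margin > 0:
            intervals = [
                (s + margin, e - margin) if (e - s) > 3 * margin else (s, e)
                for s, e in intervals
            ]
        if intervals:
            gap = max(
                (intervals[0][0],)
                + tuple(s2 - e1 for (_, e1), (s2, _) in zip(intervals, intervals[1:]))
                + (n - intervals[-1][1],)
            )
            if gap > 5.0 * fs:
                warnings.warn("no zero-velocity update in over 5 s of data; drift unbounded there")
        v = v_raw.copy()
        prev_end = 0
        for s, e in intervals:
            if s > prev_end:
                # swing [prev_end, s): velocity is the raw increment since the
                # last zero-clamped sample, minus a linear ramp removing the
                # residual seen at the stance onset (exact for constant accel
                # error over the swing)
                base = v_raw[prev_end - 1] if prev_end > 0 else np.zeros(3)
                drift = v_raw[s] - base
                m = s - prev_end + 1
                ramp = (np.arange(1, m) / m)[:, None]
                v[prev_end:s] = (v_raw[prev_end:s] - base) - drift * ramp
            v[s:e] = 0.0
            prev_end = e
        if prev_end not in (0, n):
            # trailing segment has no terminal anchor: raw increments from rest
            v[prev_end:] = v_raw[prev_end:] - v_raw[prev_end - 1]
    p = cumulative_trapezoid(v, dx=dt, axis=0, initial=0.0)
    return v, p


def register_trajectory(
    est: np.ndarray, ref: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Register an estimated trajectory to a reference frame.

    Comparing a dead-reckoned trajectory against an external reference
    (optical system, simulator truth) requires expressing both in one
    frame.  Gravity fixes the vertical axis for both systems; the azimuth
    and origin of the estimate's frame are unobservable to an inertial
    system, so registration is a single least-squares rotation about the
    vertical plus a translation — the minimal alignment any such
    comparison performs.

    Returns the registered estimate and the fitted yaw (rad).
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise InvalidInputError("trajectories must have identical shapes")
    a = est[:, :2] - est[:, :2].mean(axis=0)
    b = ref[:, :2] - ref[:, :2].mean(axis=0)
    theta = float(
        np.arctan2(
            np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]),
            np.sum(a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]),
        )
    )
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    out = est @ R.T
    out = out + (ref - out).mean(axis=0)
    return out, theta


def gait_stance_intervals(
    mask: StanceMask, fs: float, max_stance_s: float = MAX_STANCE_S
) -> List[Tuple[int, int]]:
    """Stance intervals that belong to walking; overlong ones are standing rest."""
    limit = max_stance_s * fs
    return [(s, e) for s, e in mask.intervals if (e - s) <= limit]


def segment_strides(
    mask: StanceMask,
    positions: np.ndarray,
    fs: float,
    max_stance_s: float = MAX_STANCE_S,
) -> List[Stride]:
    """Cut the position trace into strides anchored at initial contacts.

    IC = stance-interval start, FO = stance-interval end.  Stride length is
    the horizontal displacement between the median positions of consecutive
    stance intervals (medians are robust to integration ringing); clearance
    is the swing-phase vertical maximum above the mean stance-level of the
    two bounding intervals.  Stance intervals longer than ``max_stance_s``
    are treated as standing and do not anchor strides.
    """
    positions = np.asarray(positions, dtype=float)
    intervals = gait_stance_intervals(mask, fs, max_stance_s)
    if len(intervals) < 2:
        warnings.warn("fewer than two gait stance intervals; no strides segmented")
        return []
    strides: List[Stride] = []
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        med1 = np.median(positions[s1:e1], axis=0)
        med2 = np.median(positions[s2:e2], axis=0)
        length = float(np.hypot(*(med2[:2] - med1[:2])))
        cycle = (s2 - s1) / fs
        stance_time = (e1 - s1) / fs
        swing_time = cycle - stance_time
        baseline = 0.5 * (med1[2] + med2[2])
        swing_z = positions[e1:s2, 2]
        clearance = float(np.max(swing_z) - baseline) if swing_z.size else 0.0
        strides.append(
            Stride(
                start_ic=s1 / fs,
                end_ic=s2 / fs,
                stance_time=stance_time,
                swing_time=swing_time,
                cycle=cycle,
                length=length,
                speed=length / cycle,
                clearance_max=clearance,
                start_idx=int(s1),
                end_idx=int(s2),
                positions=positions[s1:s2],
            )
        )
    return strides


def initial_segment_angle(static_acc: np.ndarray, g: float = GRAVITY) -> float:
    """Sagittal inclination (rad, forward lean positive) from static accel.

    Accepts one sample (3,) or a quasi-static stretch (n, 3), which is
    averaged.  The sample must be near-static (specific-force norm within
    5% of g).
    """
    a = np.asarray(static_acc, dtype=float)
    if a.ndim == 2:
        a = a.mean(axis=0)
    norm = np.linalg.norm(a)
    if abs(norm - g) / g >= 0.05:
        raise InvalidInputError(
            f"specific-force norm {norm:.3f} deviates >5% from g; not a static sample"
        )
    return float(np.arctan2(a[0], a[2]))


def _aligned_rate_difference(
    seq_a: ImuSequence, seq_b: ImuSequence, axis: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Resample seq_b's gyro onto seq_a's clock; return (t, ω_a − ω_b) on that grid."""
    t = seq_a.t
    if abs(seq_b.t[0] - t[0]) > 0.01 or abs(seq_b.t[-1] - t[-1]) > 0.01:
        raise InvalidInputError("sequences misaligned by more than 10 ms; cannot difference")
    wb = np.interp(t, seq_b.t, seq_b.gyro[:, axis])
    return t, seq_a.gyro[:, axis] - wb


def _integrate_with_resets(
    t: np.ndarray,
    rate: np.ndarray,
    init_value: float,
    reset_times: Optional[Sequence[float]],
    mode: str = "value",
) -> np.ndarray:
    """Cumulative-trapezoid integral anchored at init_value with drift removal.

    ``mode="value"`` pins the series to ``init_value`` at every reset time
    (valid when the joint returns to its standing configuration there) by a
    piecewise-linear correction through the anchors.  ``mode="trend"``
    assumes only that the gait is cyclic: the series should repeat at
    phase-equivalent reset times, so a robust (Theil–Sen) line through the
    anchor values estimates the integration drift rate, which is then
    subtracted; the median of pairwise slopes ignores anchors that fall on
    non-steady cycles (gait start/stop transients, terminal standing).
    """
    theta = init_value + cumulative_trapezoid(rate, t, initial=0.0)
    if reset_times is None or len(reset_times) == 0:
        return theta
    rt = np.asarray(sorted(reset_times), dtype=float)
    offsets = np.interp(rt, t, theta)
    if mode == "value":
        correction = np.interp(t, rt, offsets - init_value)
        return theta - correction
    if len(rt) < 2:
        return theta
    slopes = [
        (offsets[j] - offsets[i]) / (rt[j] - rt[i])
        for i in range(len(rt))
        for j in range(i + 1, len(rt))
    ]
    drift = float(np.median(slopes))
    return theta - drift * (t - t[0])


def knee_angle(
    thigh: ImuSequence,
    shank: ImuSequence,
    init: SegmentAngles,
    flexion_axis: int = 1,
    reset_times: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Knee flexion series (rad, flexion positive) by gyro-difference integration.

    ``θ_knee(t) = ∫(ω_thigh − ω_shank)·flexion dt + θ_thigh0 − θ_shank0``.
    With sensors mounted x-anterior / y-left / z-proximal, the flexion rate
    is the *negative* mediolateral (y) rate difference, matching the
    forward-lean-positive inclination convention of
    :func:`initial_segment_angle`.

    reset_times : optional stance-midpoint times (s) at which the knee is
        assumed back at its standing angle; integration drift is removed by
        piecewise-linear detrending through those anchors.
    """
    t, dw = _aligned_rate_difference(thigh, shank, flexion_axis)
    rate = -dw
    init_value = init.theta_thigh0 - init.theta_shank0
    return _integrate_with_resets(t, rate, init_value, reset_times)


def ankle_angle(
    foot: ImuSequence,
    shank: ImuSequence,
    init: SegmentAngles,
    flexion_axis: int = 1,
    reset_times: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Ankle angle series (rad), dorsiflexion positive / plantarflexion negative.

    Foot–shank analogue of :func:`knee_angle`: plantarflexion pitches the
    foot forward (toes down), so the dorsiflexion-positive rate is
    ``θ̇_shank − θ̇_foot`` = +(ω_foot − ω_shank)·ŷ in the mounting
    convention above.  Anchored at ``θ_shank0 − θ_foot0``.  Unlike the
    knee, the ankle does not return to its standing angle mid-stance (the
    shank rotates over the planted foot), so drift removal uses the
    cyclicity-based trend mode: a robust line through the values at
    successive stance midpoints estimates the drift rate, which is
    subtracted.
    """
    t, dw = _aligned_rate_difference(foot, shank, flexion_axis)
    rate = dw  # = -( (-w_foot) - (-w_shank) ) = θ̇_shank − θ̇_foot
    init_value = init.theta_shank0 - init.theta_foot0
    return _integrate_with_resets(t, rate, init_value, reset_times, mode="trend")


def knee_rom(
    per_stride_series: Sequence[np.ndarray], in_degrees: bool = False
) -> np.ndarray:
    """Per-stride knee range of motion, degrees (max − min within the stride)."""
    roms = np.array([float(np.max(s) - np.min(s)) for s in per_stride_series])
    return roms if in_degrees else np.degrees(roms)


@dataclass
class GaitParameters:
    """Per-stride spatio-temporal parameters with mean ± SD summaries.

    All per-stride fields are 1-D arrays of equal length; ``stride_frequency``
    counts steps per minute (two steps per stride).
    """

    stride_length: np.ndarray
    stride_speed: np.ndarray
    stride_frequency: np.ndarray
    walking_cycle: np.ndarray
    stance_time: np.ndarray
    swing_time: np.ndarray
    clearance: np.ndarray
    knee_rom: Optional[np.ndarray] = None

    FIELDS = (
        "stride_length",
        "stride_speed",
        "stride_frequency",
        "walking_cycle",
        "stance_time",
        "swing_time",
        "clearance",
        "knee_rom",
    )

    def summary(self) -> dict:
        """{parameter: (mean, sample SD)} over strides (SD = 0 for one stride)."""
        out = {}
        for name in self.FIELDS:
            vals = getattr(self, name)
            if vals is None:
                continue
            vals = np.asarray(vals, dtype=float)
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            out[name] = (float(np.mean(vals)), sd)
        return out


def compute_gait_parameters(
    strides: Sequence[Stride], knee_rom_list: Optional[np.ndarray] = None
) -> GaitParameters:
    """Assemble per-stride parameter lists from segmented strides."""
    if len(strides) < 1:
        raise InvalidInputError("need at least one stride")
    if knee_rom_list is not None and len(knee_rom_list) != len(strides):
        raise InvalidInputError("knee ROM list length must match the stride count")
    cycles = np.array([s.cycle for s in strides])
    return GaitParameters(
        stride_length=np.array([s.length for s in strides]),
        stride_speed=np.array([s.speed for s in strides]),
        stride_frequency=120.0 / cycles,
        walking_cycle=cycles,
        stance_time=np.array([s.stance_time for s in strides]),
        swing_time=np.array([s.swing_time for s in strides]),
        clearance=np.array([s.clearance_max for s in strides]),
        knee_rom=None if knee_rom_list is None else np.asarray(knee_rom_list, dtype=float),
    )
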