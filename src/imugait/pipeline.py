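"""End-to-end session analysis: calibrate → fuse → detect → integrate → report.

The pipeline wires the library stages together for a standard lower-limb
recording (one sensor per foot, optionally shank and thigh, both sides).
Each recording is assumed to begin with a quasi-static standing stretch,
which anchors the initial attitude, the gyro-bias estimate and the static
segment inclinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .calibration import AccelCalibration, MagCalibration, apply_accel_calibration, apply_mag_calibration
from .errors import ConfigError
from .fusion import FusionConfig, fuse_sequence, initial_orientation
from .quaternion import rotate_vector
from .gait import (
    GaitParameters,
    SegmentAngles,
    Stride,
    compute_gait_parameters,
    gait_stance_intervals,
    initial_segment_angle,
    integrate_position_zvu,
    knee_angle,
    ankle_angle,
    knee_rom,
    remove_gravity,
    segment_strides,
)
from .io import write_json_report
from .sequence import ImuSequence
from .stance import StanceDetectorConfig, StanceMask, detect_stance
from .stats import AnovaTable, bilateral_rom_anova

__all__ = ["PipelineConfig", "SideResult", "GaitReport", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Knobs of the full analysis chain."""

    detector: StanceDetectorConfig = field(default_factory=StanceDetectorConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    accel_cal: Optional[AccelCalibration] = None
    mag_cal: Optional[MagCalibration] = None
    bias_window_s: float = 1.0  # initial stretch used for gyro-bias / attitude init
    #: None = compute joint angles when thigh+shank streams are present;
    #: True = require them (ConfigError if missing); False = skip
    compute_joint_angles: Optional[bool] = None
    seed: int = 0


@dataclass
class SideResult:
    """Per-side artefacts of a pipeline run."""

    side: str
    stance: StanceMask
    quats: np.ndarray
    velocity: np.ndarray
    position: np.ndarray
    strides: List[Stride]
    parameters: Optional[GaitParameters]
    knee: Optional[np.ndarray] = None
    ankle: Optional[np.ndarray] = None
    knee_rom: Optional[np.ndarray] = None


@dataclass
class GaitReport:
    """Session-level result: both sides plus the bilateral symmetry test."""

    sides: Dict[str, SideResult]
    anova: Optional[AnovaTable] = None

    def summary(self) -> dict:
        doc = {}
        for side, res in self.sides.items():
            doc[side] = res.parameters.summary() if res.parameters else {}
        if self.anova is not None:
            doc["bilateral_knee_rom_anova"] = {
                "F": self.anova.f,
                "p": self.anova.p,
                "df": [self.anova.df_columns, self.anova.df_error],
            }
        return doc


def _calibrated(seq: ImuSequence, cfg: PipelineConfig) -> ImuSequence:
    acc = seq.acc
    mag = seq.mag
    if cfg.accel_cal is not None:
        acc = apply_accel_calibration(acc, cfg.accel_cal)
    if cfg.mag_cal is not None and mag is not None:
        mag = apply_mag_calibration(mag, cfg.mag_cal)
    return seq.replace(acc=acc, mag=mag)


def _debias_gyro(seq: ImuSequence, window_s: float) -> ImuSequence:
    """Remove the mean angular rate over the initial standing stretch."""
    n = max(3, int(round(window_s * seq.fs)))
    bias = seq.gyro[: min(n, len(seq))].mean(axis=0)
    return seq.replace(gyro=seq.gyro - bias)


def run_pipeline(
    sequences: Dict[str, ImuSequence], cfg: Optional[PipelineConfig] = None
) -> GaitReport:
    """Analyse a session given per-segment raw sequences keyed by segment label.

    Requires ``foot_L`` and/or ``foot_R``; knee/ankle angles additionally
    need the same-side ``thigh_*`` and ``shank_*`` streams.  Deterministic
    given inputs and configuration.
    """
    cfg = cfg or PipelineConfig()
    feet = [s for s in ("L", "R") if f"foot_{s}" in sequences]
    if not feet:
        raise ConfigError("no foot sensor stream supplied; cannot analyse gait")

    cal: Dict[str, ImuSequence] = {}
    for name, seq in sequences.items():
        cal[name] = _debias_gyro(_calibrated(seq, cfg), cfg.bias_window_s)

    n_static = max(3, int(round(cfg.bias_window_s * cal[f"foot_{feet[0]}"].fs)))
    sides: Dict[str, SideResult] = {}
    for side in feet:
        foot = cal[f"foot_{side}"]
        stance = detect_stance(foot, cfg.detector)
        # second-pass gyro debias: the foot is truly stationary throughout
        # stance, so the stance-sample mean rate is a far better bias
        # estimate than the initial standing stretch alone
        stance_idx = np.flatnonzero(stance.mask)
        if stance_idx.size >= 100:
            foot = foot.replace(gyro=foot.gyro - foot.gyro[stance_idx].mean(axis=0))
        use_stance_ref = stance_idx.size >= 100
        q0 = initial_orientation(
            foot,
            n_static=n_static,
            use_mag=cfg.fusion.use_mag and foot.mag is not None,
            acc_mean=foot.acc[stance_idx].mean(axis=0) if use_stance_ref else None,
            mag_mean=(
                foot.mag[stance_idx].mean(axis=0)
                if use_stance_ref and foot.mag is not None
                else None
            ),
        )
        # heading reference anchored to the stance-averaged field: the foot
        # revisits the standing orientation every stance, so this mean is
        # both low-noise and consistent with the initial attitude above
        b_ref = None
        if cfg.fusion.use_mag and foot.mag is not None:
            idx = stance_idx if use_stance_ref else np.arange(n_static)
            m_mean = foot.mag[idx].mean(axis=0)
            if np.linalg.norm(m_mean) > 0:
                b_ref = rotate_vector(q0, m_mean / np.linalg.norm(m_mean))
        quats = fuse_sequence(foot, cfg.fusion, q0=q0, b_ref=b_ref)
        lin_acc = remove_gravity(foot.acc, quats)
        vel, pos = integrate_position_zvu(lin_acc, stance, foot.fs)
        strides = segment_strides(stance, pos, foot.fs)

        knee = ankle = roms = None
        thigh_key, shank_key = f"thigh_{side}", f"shank_{side}"
        have_segments = thigh_key in cal and shank_key in cal
        if cfg.compute_joint_angles is True and not have_segments:
            raise ConfigError(
                f"joint angles requested but {thigh_key}/{shank_key} streams are missing"
            )
        if cfg.compute_joint_angles is not False and have_segments:
            thigh, shank = cal[thigh_key], cal[shank_key]
            init = SegmentAngles(
                theta_thigh0=initial_segment_angle(thigh.acc[:n_static]),
                theta_shank0=initial_segment_angle(shank.acc[:n_static]),
                theta_foot0=initial_segment_angle(foot.acc[:n_static]),
            )
            gait_ivals = gait_stance_intervals(stance, foot.fs)
            mids = [foot.t[(s + e) // 2] for s, e in gait_ivals]
            knee = knee_angle(thigh, shank, init, reset_times=mids)
            ankle = ankle_angle(foot, shank, init, reset_times=mids)
            if strides:
                roms = knee_rom([knee[s.start_idx : s.end_idx] for s in strides])
        params = compute_gait_parameters(strides, roms) if strides else None
        sides[side] = SideResult(
            side=side,
            stance=stance,
            quats=quats,
            velocity=vel,
            position=pos,
            strides=strides,
            parameters=params,
            knee=knee,
            ankle=ankle,
            knee_rom=roms,
        )

    anova = None
    if (
        "L" in sides
        and "R" in sides
        and sides["L"].knee_rom is not None
        and sides["R"].knee_rom is not None
        and min(len(sides["L"].knee_rom), len(sides["R"].knee_rom)) >= 2
    ):
        anova = bilateral_rom_anova(sides["L"].knee_rom, sides["R"].knee_rom)
    return GaitReport(sides=sides, anova=anova)


def write_report(report: GaitReport, outdir: Path) -> None:
    """Per-stride CSV per side, a JSON summary, and the ANOVA table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for side, res in report.sides.items():
        if not res.strides:
            continue
        rows = []
        for i, s in enumerate(res.strides):
            row = {
                "stride": i,
                "ic_s": s.start_ic,
                "fo_s": s.start_ic + s.stance_time,
                "cycle_s": s.cycle,
                "stance_s": s.stance_time,
                "swing_s": s.swing_time,
                "length_m": s.length,
                "speed_mps": s.speed,
                "clearance_m": s.clearance_max,
            }
            if res.knee_rom is not None:
                row["knee_rom_deg"] = float(res.knee_rom[i])
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / f"strides_{side}.csv", index=False)
    write_json_report(report.summary(), outdir / "summary.json")
    if report.anova is not None:
        report.anova.to_frame().to_csv(outdir / "anova_knee_rom.csv", index=False)
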