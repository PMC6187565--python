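"""Delimited-text I/O for sensor logs, masks, calibrations and reports.

Log format: CSV with a header row, columns ``t, ax, ay, az, gx, gy, gz``
and optionally ``mx, my, mz`` — SI units (s, m/s², rad/s; magnetometer in
any consistent unit).  Calibration results round-trip through YAML with
documented keys; stance masks and intervals are two-column CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .calibration import AccelCalibration, MagCalibration, NonOrthoAngles
from .errors import ParseError
from .sequence import ImuSequence
from .stance import StanceMask, mask_from_intervals

__all__ = [
    "read_imu_log",
    "write_imu_log",
    "read_points",
    "write_points",
    "save_calibration",
    "load_calibration",
    "write_stance_mask",
    "read_stance_mask",
]

_REQUIRED = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
_MAG = ["mx", "my", "mz"]


def read_imu_log(path: Union[str, Path], fs: float = 100.0, segment: str | None = None) -> ImuSequence:
    """Parse and validate a delimited-text sensor log.

    Raises :class:`ParseError` naming the first offending line for missing
    columns, non-finite values, or non-monotone timestamps.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: cannot parse as CSV ({exc})") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    has_mag = all(c in df.columns for c in _MAG)
    cols = _REQUIRED + (_MAG if has_mag else [])
    values = df[cols].to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise ParseError(f"{path}: non-finite value at data line {row + 2}")  # +header, 1-based
    t = values[:, 0]
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ParseError(f"{path}: non-monotone timestamp at data line {row + 2}")
    return ImuSequence(
        t=t,
        acc=values[:, 1:4],
        gyro=values[:, 4:7],
        mag=values[:, 7:10] if has_mag else None,
        fs=fs,
        segment=segment,
    )


def write_imu_log(seq: ImuSequence, path: Union[str, Path]) -> None:
    data = {"t": seq.t}
    for i, c in enumerate(("ax", "ay", "az")):
        data[c] = seq.acc[:, i]
    for i, c in enumerate(("gx", "gy", "gz")):
        data[c] = seq.gyro[:, i]
    if seq.mag is not None:
        for i, c in enumerate(_MAG):
            data[c] = seq.mag[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_points(path: Union[str, Path]) -> np.ndarray:
    """Read a calibration point cloud (header ``x,y,z``, one vector per row)."""
    df = pd.read_csv(path)
    for c in ("x", "y", "z"):
        if c not in df.columns:
            raise ParseError(f"{path}: missing column {c!r}")
    return df[["x", "y", "z"]].to_numpy(dtype=float)


def write_points(points: np.ndarray, path: Union[str, Path]) -> None:
    pd.DataFrame(np.asarray(points, dtype=float), columns=["x", "y", "z"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def save_calibration(
    path: Union[str, Path],
    accel: AccelCalibration | None = None,
    mag: MagCalibration | None = None,
) -> None:
    """Serialise calibration results to YAML (angles in rad, bias in m/s²)."""
    doc = {}
    if accel is not None:
        doc["accelerometer"] = {
            "nonortho_rad": {
                "alpha": float(accel.angles.alpha),
                "beta": float(accel.angles.beta),
                "gamma": float(accel.angles.gamma),
            },
            "bias_mps2": [float(v) for v in accel.bias],
            "gravity_mps2": float(accel.g_mag),
        }
    if mag is not None:
        doc["magnetometer"] = {
            "hard_iron": [float(v) for v in mag.offset],
            "soft_iron": [[float(v) for v in row] for row in mag.matrix],
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_calibration(
    path: Union[str, Path],
) -> Tuple[AccelCalibration | None, MagCalibration | None]:
    doc = yaml.safe_load(Path(path).read_text())
    accel = mag = None
    if doc and "accelerometer" in doc:
        a = doc["accelerometer"]
        ang = a["nonortho_rad"]
        accel = AccelCalibration(
            angles=NonOrthoAngles(ang["alpha"], ang["beta"], ang["gamma"]),
            bias=np.array(a["bias_mps2"], dtype=float),
            g_mag=float(a.get("gravity_mps2", 9.81)),
        )
    if doc and "magnetometer" in doc:
        m = doc["magnetometer"]
        mag = MagCalibration(
            offset=np.array(m["hard_iron"], dtype=float),
            matrix=np.array(m["soft_iron"], dtype=float),
        )
    return accel, mag


def write_stance_mask(mask: StanceMask, path: Union[str, Path], fs: float = 100.0) -> None:
    """Per-sample flags plus a sibling ``*.intervals.csv`` with times in s."""
    path = Path(path)
    pd.DataFrame(
        {"sample_index": np.arange(len(mask)), "stance_flag": mask.mask.astype(int)}
    ).to_csv(path, index=False)
    ivals = pd.DataFrame(
        [{"start_s": s / fs, "end_s": e / fs} for s, e in mask.intervals]
    )
    ivals.to_csv(path.with_suffix(".intervals.csv"), index=False)


def read_stance_mask(path: Union[str, Path]) -> StanceMask:
    df = pd.read_csv(path)
    mask = df["stance_flag"].to_numpy(dtype=bool)
    return StanceMask.from_mask(mask)


def write_json_report(doc: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
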