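"""The in-memory container for one body-segment sensor stream."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidInputError

SEGMENT_LABELS = ("foot_L", "foot_R", "shank_L", "shank_R", "thigh_L", "thigh_R")

GRAVITY = 9.81  # m/s^2, global frame z-up


@dataclass
class ImuSequence:
    """Uniformly sampled tri-axial accel/gyro(/mag) stream for one sensor.

    Attributes
    ----------
    t : (n,) strictly increasing timestamps, s.
    acc : (n, 3) specific force in the sensor frame, m/s^2.
    gyro : (n, 3) angular rate in the sensor frame, rad/s.
    mag : optional (n, 3) magnetic field, arbitrary but consistent units.
    fs : nominal sampling rate, Hz.
    segment : body-segment label (``foot_L`` ... ``thigh_R``) or None.
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    mag: Optional[np.ndarray] = None
    fs: float = 100.0
    segment: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        n = self.t.shape[0]
        for name in ("acc", "gyro"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise InvalidInputError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        if self.mag is not None and self.mag.shape != (n, 3):
            raise InvalidInputError(f"mag must have shape ({n}, 3), got {self.mag.shape}")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0))
                raise InvalidInputError(f"timestamps not strictly increasing at sample {bad + 1}")
            med = float(np.median(dt))
            if abs(med - 1.0 / self.fs) > 0.1 / self.fs:
                raise InvalidInputError(
                    f"median sample period {med:.6f}s deviates >10% from nominal 1/fs={1.0 / self.fs:.6f}s"
                )
        if self.segment is not None and self.segment not in SEGMENT_LABELS:
            raise InvalidInputError(f"unknown segment label {self.segment!r}")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    @property
    def dt(self) -> float:
        """Nominal sample period, s."""
        return 1.0 / self.fs

    def replace(self, **kwargs) -> "ImuSequence":
        """Copy with some channels substituted (used by calibration stages)."""
        data = dict(
            t=self.t, acc=self.acc, gyro=self.gyro, mag=self.mag, fs=self.fs, segment=self.segment
        )
        data.update(kwargs)
        return ImuSequence(**data)
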