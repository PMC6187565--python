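"""Stance-phase detection for zero-velocity updates.

Two per-sample criteria are fused at the decision level:

* the moving variance (window N) of the normalised squared acceleration norm
  ``V = (ax/g)² + (ay/g)² + (az/g)²`` — near-constant (≈1) when the foot is
  on the ground, strongly fluctuating in swing; and
* the windowed angular-rate energy
  ``E_j = (1/(σω² W)) Σ_{i=j-W+1..j} ‖ω_i‖²`` — of order one at rest when
  σω² is the rest-level second moment, and orders of magnitude larger in
  swing.

A sample is stance when both statistics fall below their thresholds.  Both
windows are trailing (causal), which erodes the leading edge of every
stance interval by up to one window length; the detector compensates that
known group delay by advancing each onset, then debounces short runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import InvalidInputError
from .sequence import GRAVITY, ImuSequence

__all__ = [
    "StanceDetectorConfig",
    "StanceMask",
    "accel_norm_ratio",
    "moving_variance",
    "gyro_energy",
    "detect_stance",
    "zvu_intervals",
    "mask_from_intervals",
]


@dataclass
class StanceDetectorConfig:
    """Thresholds and windows of the two-criterion stance detector.

    lambda1 : threshold on the moving variance of V (dimensionless).
    lambda2 : threshold on the normalised angular-rate energy.
    W, N : energy / variance window lengths, samples.
    sigma_omega2 : gyroscope rest-level second moment, (rad/s)²; estimated
        from the first second of data when None.
    min_stance : minimum stance duration, s (shorter runs are discarded).
    onset_advance : samples by which each detected onset is shifted earlier
        to undo the trailing-window group delay; defaults to
        ``max(N, W) - 1`` when None, 0 disables.
    """

    lambda1: float = 0.02
    lambda2: float = 1.5
    W: int = 15
    N: int = 15
    sigma_omega2: Optional[float] = None
    min_stance: float = 0.1
    onset_advance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise InvalidInputError("thresholds must be positive")
        if self.W < 3 or self.N < 3:
            raise InvalidInputError("windows must span at least 3 samples")
        if self.sigma_omega2 is not None and self.sigma_omega2 <= 0:
            raise InvalidInputError("sigma_omega2 must be positive")


@dataclass
class StanceMask:
    """Binary stance indicator plus its maximal-run intervals.

    ``mask`` is a boolean per-sample array; ``intervals`` is the equivalent
    sorted list of disjoint half-open ``(start, end)`` sample ranges.
    """

    mask: np.ndarray
    intervals: List[Tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "StanceMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask=mask, intervals=_runs(mask))

    def __len__(self) -> int:
        return int(self.mask.shape[0])


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as half-open index ranges."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    padded = np.concatenate([[False], m, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def mask_from_intervals(intervals: List[Tuple[int, int]], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def accel_norm_ratio(acc: np.ndarray, g: float = GRAVITY) -> np.ndarray:
    """Squared acceleration norm in gravity units, per sample."""
    if g <= 0:
        raise InvalidInputError("g must be positive")
    acc = np.asarray(acc, dtype=float)
    return np.sum((acc / g) ** 2, axis=-1)


def moving_variance(series: np.ndarray, N: int) -> np.ndarray:
    """Trailing-window population variance; the first N-1 samples are NaN (warm-up)."""
    series = np.asarray(series, dtype=float)
    if N < 1 or N > series.shape[0]:
        raise InvalidInputError(f"window N={N} invalid for series of length {series.shape[0]}")
    windows = np.lib.stride_tricks.sliding_window_view(series, N)
    out = np.full(series.shape[0], np.nan)
    out[N - 1 :] = windows.var(axis=-1)
    return out


def gyro_energy(gyro: np.ndarray, W: int, sigma_omega2: float) -> np.ndarray:
    """Trailing-window angular-rate energy normalised by σω²·W; warm-up is NaN."""
    gyro = np.asarray(gyro, dtype=float)
    if sigma_omega2 <= 0:
        raise InvalidInputError("sigma_omega2 must be positive")
    n = gyro.shape[0]
    if W < 1 or W > n:
        raise InvalidInputError(f"window W={W} invalid for sequence of length {n}")
    sq = np.sum(gyro * gyro, axis=-1)
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    out = np.full(n, np.nan)
    out[W - 1 :] = (csum[W:] - csum[:-W]) / (sigma_omega2 * W)
    return out


def rest_gyro_second_moment(gyro: np.ndarray, fs: float) -> float:
    """Mean squared rate norm over the first second — the rest-level energy scale."""
    n = max(3, int(round(fs)))
    sq = np.sum(np.asarray(gyro, dtype=float)[:n] ** 2, axis=-1)
    return float(np.mean(sq))


def detect_stance(seq: ImuSequence, cfg: StanceDetectorConfig | None = None) -> StanceMask:
    """Classify every sample of a foot-sensor stream as stance or swing.

    Returns a :class:`StanceMask`; an empty mask (no stance found) is
    reported with a warning, not an error.
    """
    cfg = cfg or StanceDetectorConfig()
    n = len(seq)
    if n <= max(cfg.W, cfg.N):
        raise InvalidInputError("sequence shorter than the detector windows")
    V = accel_norm_ratio(seq.acc)
    var = moving_variance(V, cfg.N)
    sigma2 = cfg.sigma_omega2
    if sigma2 is None:
        sigma2 = rest_gyro_second_moment(seq.gyro, seq.fs)
        if sigma2 <= 0:
            sigma2 = 1e-12
    energy = gyro_energy(seq.gyro, cfg.W, sigma2)
    with np.errstate(invalid="ignore"):
        raw = (var < cfg.lambda1) & (energy < cfg.lambda2)

    advance = cfg.onset_advance
    if advance is None:
        advance = max(cfg.N, cfg.W) - 1
    intervals = _runs(raw)
    if advance > 0:
        intervals = [(max(0, s - advance), e) for s, e in intervals]
    # morphological closing after the shift: a noise spike poisons every
    # window it sits in, punching a hole up to one window wide into an
    # interval — and no true swing is shorter than min_stance anyway
    fill = int(round(cfg.min_stance * seq.fs))
    merged: List[Tuple[int, int]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < fill:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    intervals = [(s, e) for s, e in merged if e - s >= fill]
    if not intervals:
        warnings.warn("no stance interval detected; zero-velocity updates unavailable")
    return StanceMask(mask=mask_from_intervals(intervals, n), intervals=intervals)


def zvu_intervals(mask: StanceMask) -> List[Tuple[int, int]]:
    """Half-open index ranges in which zero-velocity updates are valid."""
    return list(mask.intervals)
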