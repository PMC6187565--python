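"""Cohort summaries and one-way ANOVA for bilateral gait symmetry.

The symmetry question — do left and right knees cover the same range of
motion? — is assessed with a one-way analysis of variance over per-stride
bilateral ROM pairs: stride index defines the group (so k strides give k
groups of 2, with k-1 between-group and k within-group degrees of freedom).
Standard frequentist semantics are used throughout: a small p-value is
evidence *against* the null hypothesis of equal group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError
from .gait import GaitParameters

__all__ = [
    "AnovaTable",
    "one_way_anova",
    "anova_from_ss",
    "bilateral_rom_anova",
    "summarize_cohort",
]


@dataclass
class AnovaTable:
    """Classic one-way ANOVA decomposition (Columns / Error / Total rows)."""

    ss_columns: float
    ss_error: float
    df_columns: int
    df_error: int

    @property
    def ss_total(self) -> float:
        return self.ss_columns + self.ss_error

    @property
    def df_total(self) -> int:
        return self.df_columns + self.df_error

    @property
    def ms_columns(self) -> float:
        return self.ss_columns / self.df_columns

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    @property
    def f(self) -> float:
        return self.ms_columns / self.ms_error

    @property
    def p(self) -> float:
        return float(sps.f.sf(self.f, self.df_columns, self.df_error))

    def to_frame(self) -> pd.DataFrame:
        """Source/SS/df/MS/F/p table in the conventional row order."""
        return pd.DataFrame(
            [
                {
                    "Source": "Columns",
                    "SS": self.ss_columns,
                    "df": self.df_columns,
                    "MS": self.ms_columns,
                    "F": self.f,
                    "p": self.p,
                },
                {
                    "Source": "Error",
                    "SS": self.ss_error,
                    "df": self.df_error,
                    "MS": self.ms_error,
                    "F": np.nan,
                    "p": np.nan,
                },
                {
                    "Source": "Total",
                    "SS": self.ss_total,
                    "df": self.df_total,
                    "MS": np.nan,
                    "F": np.nan,
                    "p": np.nan,
                },
            ]
        )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """One-way ANOVA from raw group samples.

    Requires at least two groups, every group non-empty, and at least one
    group with two or more observations (else the error term vanishes).
    Raises :class:`InvalidInputError` when all observations are identical
    (F undefined).
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise InvalidInputError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise InvalidInputError("every group needs at least one observation")
    all_obs = np.concatenate(arrays)
    n_total = all_obs.size
    if n_total - len(arrays) < 1:
        raise InvalidInputError("at least one group needs two or more observations")
    grand = all_obs.mean()
    ss_columns = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_error = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    if ss_error == 0.0 and ss_columns == 0.0:
        raise InvalidInputError("all observations identical: F statistic undefined")
    return AnovaTable(
        ss_columns=ss_columns,
        ss_error=ss_error,
        df_columns=len(arrays) - 1,
        df_error=n_total - len(arrays),
    )


def anova_from_ss(
    ss_columns: float, df_columns: int, ss_error: float, df_error: int
) -> AnovaTable:
    """Deterministically complete an ANOVA table from its (SS, df) pairs."""
    if df_columns < 1 or df_error < 1:
        raise InvalidInputError("degrees of freedom must be positive")
    return AnovaTable(
        ss_columns=float(ss_columns),
        ss_error=float(ss_error),
        df_columns=int(df_columns),
        df_error=int(df_error),
    )


def bilateral_rom_anova(left_rom: np.ndarray, right_rom: np.ndarray) -> AnovaTable:
    """Bilateral knee-ROM symmetry ANOVA with stride-index grouping.

    Pairs the k-th left stride with the k-th right stride; k stride pairs
    give k groups of two (df between = k−1, df within = k).
    """
    left_rom = np.asarray(left_rom, dtype=float)
    right_rom = np.asarray(right_rom, dtype=float)
    k = min(left_rom.size, right_rom.size)
    if k < 2:
        raise InvalidInputError("need at least two stride pairs")
    groups = [[left_rom[i], right_rom[i]] for i in range(k)]
    return one_way_anova(groups)


def summarize_cohort(subjects: Sequence[GaitParameters]) -> pd.DataFrame:
    """Across-subject mean ± sample SD of each gait parameter.

    Each subject contributes the mean of their per-stride values; columns
    are ``mean`` and ``sd`` (SD = 0 for a single subject), one row per
    parameter.
    """
    if len(subjects) < 1:
        raise InvalidInputError("need at least one subject")
    rows: Dict[str, Tuple[float, float]] = {}
    for name in GaitParameters.FIELDS:
        vals = [
            float(np.mean(getattr(s, name)))
            for s in subjects
            if getattr(s, name) is not None
        ]
        if not vals:
            continue
        arr = np.array(vals)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        rows[name] = (float(arr.mean()), sd)
    return pd.DataFrame(
        [{"parameter": k, "mean": v[0], "sd": v[1]} for k, v in rows.items()]
    ).set_index("parameter")
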