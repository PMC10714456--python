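"""Period-structured survival cohorts in counting-process form.

A cohort table holds one row per subject per follow-up interval, with
half-open intervals ``[entry_time, exit_time)`` measured in months from the
current period's time origin; the event indicator refers to the interval's
exit. Update-period datasets (``period_u``) are self-contained after their
time origin has been reset to the period start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RESERVED_COLUMNS",
    "CohortTable",
    "CohortValidationError",
    "PeriodSchedule",
    "read_cohort",
    "write_cohort",
    "reset_time_origin",
    "administrative_censor",
]

#: Columns every cohort CSV must carry, in canonical order; all remaining
#: columns are treated as covariates.
RESERVED_COLUMNS = ("sim_id", "subject_id", "period_u", "entry_time", "exit_time", "event")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the counting-process invariants.

    Carries row-level diagnostics in ``.details`` (a list of strings naming
    the offending rows).
    """

    def __init__(self, message: str, details: Sequence[str] = ()):
        super().__init__(message if not details else f"{message}: {'; '.join(details[:10])}")
        self.details = list(details)


@dataclass(frozen=True)
class PeriodSchedule:
    """Timing of the update/evaluate cycle.

    Parameters
    ----------
    period_length : float
        Length of one updating period in months (a quarter by default).
    n_periods : int
        Number of updating periods after development (period 0).
    horizon_v : float
        Prediction horizon in months at which survival is predicted and
        evaluated out of sample.
    """

    period_length: float = 3.0
    n_periods: int = 5
    horizon_v: float = 3.0

    def __post_init__(self):
        if self.period_length <= 0 or self.horizon_v <= 0 or self.n_periods < 1:
            raise ValueError("period_length, horizon_v must be > 0 and n_periods >= 1")
        if self.horizon_v > self.period_length:
            raise ValueError(
                "prediction horizon exceeds the follow-up available within one period"
            )


class CohortTable:
    """Validated counting-process survival records for one or more periods.

    Wraps a :class:`pandas.DataFrame` with the reserved columns of
    :data:`RESERVED_COLUMNS` plus named covariate columns (by default
    ``x1`` age in decades, ``x2`` continuous biomarker, ``x3`` binary
    comorbidity, ``x4`` binary treatment; any numeric extras are accepted).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing required column(s) {missing}")
        covs = [c for c in df.columns if c not in RESERVED_COLUMNS]
        self._df = df.reset_index(drop=True)
        self._covariates = covs
        if validate:
            self._validate()

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def covariates(self) -> list[str]:
        """Names of the covariate columns, in table order."""
        return list(self._covariates)

    @property
    def n_rows(self) -> int:
        return len(self._df)

    @property
    def n_events(self) -> int:
        return int(self._df["event"].sum())

    @property
    def total_followup(self) -> float:
        """Total person-time, in months."""
        return float((self._df["exit_time"] - self._df["entry_time"]).sum())

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        a = self.canonical_order().df
        b = other.canonical_order().df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        return bool(np.allclose(a.to_numpy(float), b.to_numpy(float)))

    def canonical_order(self) -> "CohortTable":
        """Rows sorted by (sim_id, subject_id, entry_time) for stable output."""
        out = self._df.sort_values(
            ["sim_id", "subject_id", "entry_time"], kind="mergesort"
        ).reset_index(drop=True)
        return CohortTable(out, validate=False)

    def select(self, mask) -> "CohortTable":
        return CohortTable(self._df.loc[mask].reset_index(drop=True), validate=False)

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        df = self._df
        problems: list[str] = []
        for col in list(RESERVED_COLUMNS) + self._covariates:
            if not pd.api.types.is_numeric_dtype(df[col]):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[coerced.isna()].tolist()
                raise CohortValidationError(
                    f"non-numeric values in column '{col}'", [f"row {i}" for i in bad]
                )
        bad = df.index[~(df["entry_time"] >= 0)].tolist()
        problems += [f"row {i}: entry_time < 0" for i in bad]
        bad = df.index[~(df["exit_time"] > df["entry_time"])].tolist()
        problems += [f"row {i}: exit_time <= entry_time" for i in bad]
        bad = df.index[~df["event"].isin([0, 1])].tolist()
        problems += [f"row {i}: event not in {{0,1}}" for i in bad]
        if self._covariates:
            finite = np.isfinite(df[self._covariates].to_numpy(float)).all(axis=1)
            problems += [f"row {i}: non-finite covariate" for i in df.index[~finite]]
        dup = df.duplicated(subset=["sim_id", "subject_id", "entry_time"], keep=False)
        if dup.any():
            problems += [
                f"row {i}: duplicate (sim_id, subject_id, entry_time)"
                for i in df.index[dup]
            ]
        if problems:
            raise CohortValidationError("invalid cohort table", problems)


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV (UTF-8, header row) and validate it.

    The file must contain the reserved columns followed by covariate
    columns; rows violating the counting-process invariants are rejected
    with row-level diagnostics.
    """
    df = pd.read_csv(path)
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV sorted by (sim_id, subject_id, entry_time).

    The sort makes output byte-stable for identical tables regardless of
    in-memory row order.
    """
    out = cohort.canonical_order().df
    cols = list(RESERVED_COLUMNS) + cohort.covariates
    out[cols].to_csv(path, index=False)


def reset_time_origin(cohort: CohortTable, origin: float) -> CohortTable:
    """Shift the time origin: subtract ``origin`` from entry and exit times.

    Events and covariates are untouched. ``origin`` may be negative (which
    undoes a previous reset); it must not exceed any entry time, so that
    entry times stay non-negative.
    """
    df = cohort.df
    if len(df) and origin > df["entry_time"].min():
        raise ValueError(
            f"origin {origin} exceeds the minimum entry_time {df['entry_time'].min()}"
        )
    out = df.copy()
    out["entry_time"] = out["entry_time"] - origin
    out["exit_time"] = out["exit_time"] - origin
    return CohortTable(out, validate=False)


def administrative_censor(cohort: CohortTable, cutoff: float) -> CohortTable:
    """Censor all follow-up at ``cutoff`` months from the period origin.

    Rows with ``exit_time > cutoff`` are truncated to the cutoff with
    ``event = 0``; rows exiting at or before the cutoff are unchanged. Rows
    entering at or after the cutoff would have no follow-up left and are
    dropped.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    df = cohort.df.copy()
    df = df[df["entry_time"] < cutoff].reset_index(drop=True)
    over = df["exit_time"] > cutoff
    df.loc[over, "exit_time"] = cutoff
    df.loc[over, "event"] = 0
    return CohortTable(df, validate=False)
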