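"""Cohort I/O, descriptive statistics and rank correlation.

The cohort CSV schema is one row per participant: a ``participant_id``
column, the 18 measurement columns ``{field}_{mode}`` for field in
``ratio_R, ratio_L, away_R, away_L, toward_R, toward_L`` and mode in
``60, 180, 300``, plus an optional ``group`` label.  Values use '.' as the
decimal separator; results are written at 8-decimal precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .isokinetic_model import (
    MEASUREMENT_FIELDS,
    MODES,
    EvaluationBreakdown,
    HierarchicalModel,
    ParticipantMeasurements,
)

__all__ = [
    "MEASUREMENT_COLUMNS",
    "CohortTable",
    "SummaryStats",
    "CohortFormatError",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_results_csv",
    "evaluate_cohort",
    "descriptive_stats",
    "spearman",
    "summarize_groups",
    "load_reference_outcomes",
]

MEASUREMENT_COLUMNS: tuple[str, ...] = tuple(
    f"{f}_{m}" for m in MODES for f in MEASUREMENT_FIELDS
)

RESULT_COLUMNS: tuple[str, ...] = tuple(
    c for m in MODES for c in (f"e_MT_{m}", f"e_RT_{m}", f"e_K{m}")
) + ("final_score",)

_FLOAT_FMT = "%.8f"


class CohortFormatError(ValueError):
    """The cohort file violates the documented schema."""


@dataclass
class CohortTable:
    """Participant measurements plus optional group labels."""

    participants: list[ParticipantMeasurements]
    groups: dict[str, str]  # participant_id -> group label, may be empty

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(f"duplicate participant_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.participants)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            row: dict = {"participant_id": p.participant_id, **p.flat()}
            if p.participant_id in self.groups:
                row["group"] = self.groups[p.participant_id]
            rows.append(row)
        return pd.DataFrame(rows)


def read_cohort_csv(path: str) -> CohortTable:
    """Read a cohort CSV, validating the schema cell by cell.

    Raises :class:`CohortFormatError` naming the offending row/column for
    unknown or missing columns, non-numeric cells and missing values.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise CohortFormatError(f"{path}: empty cohort file") from None
    if df.empty:
        raise CohortFormatError(f"{path}: cohort has no data rows")
    cols = list(df.columns)
    missing = [c for c in ("participant_id", *MEASUREMENT_COLUMNS) if c not in cols]
    if missing:
        raise CohortFormatError(f"{path}: missing required columns {missing}")
    unknown = [
        c for c in cols if c not in ("participant_id", "group", *MEASUREMENT_COLUMNS)
    ]
    if unknown:
        raise CohortFormatError(f"{path}: unknown columns {unknown}")

    participants = []
    groups: dict[str, str] = {}
    for idx, raw in df.iterrows():
        pid = str(raw["participant_id"])
        values: dict[str, float] = {}
        for col in MEASUREMENT_COLUMNS:
            cell = raw[col]
            if pd.isna(cell) or str(cell).strip() == "":
                raise CohortFormatError(
                    f"{path}: row {idx + 2} (participant {pid!r}): missing value in {col!r}"
                )
            try:
                values[col] = float(cell)
            except ValueError:
                raise CohortFormatError(
                    f"{path}: row {idx + 2} (participant {pid!r}): "
                    f"non-numeric value {cell!r} in {col!r}"
                ) from None
        participants.append(ParticipantMeasurements.from_flat(pid, values))
        if "group" in cols and not pd.isna(raw["group"]):
            groups[pid] = str(raw["group"])
    return CohortTable(participants=participants, groups=groups)


def write_cohort_csv(cohort: CohortTable, path: str) -> None:
    cohort.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def evaluate_cohort(
    model: HierarchicalModel, cohort: CohortTable
) -> list[EvaluationBreakdown]:
    return [model.evaluate_participant(p) for p in cohort.participants]


def write_results_csv(breakdowns: Iterable[EvaluationBreakdown], path: str) -> None:
    rows = [{"participant_id": b.participant_id, **b.flat()} for b in breakdowns]
    df = pd.DataFrame(rows, columns=("participant_id", *RESULT_COLUMNS))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass(frozen=True)
class SummaryStats:
    """Mean/SD and five-number summary of a score sample.

    ``sd`` is the sample standard deviation (n−1 denominator) and is ``None``
    for a single observation; quartiles use linear interpolation between
    order statistics (type-7), the default of most scientific software.
    """

    n: int
    mean: float
    sd: float | None
    min: float
    q1: float
    median: float
    q3: float
    max: float


def descriptive_stats(values: Sequence[float]) -> SummaryStats:
    a = np.asarray(list(values), dtype=float)
    if a.size == 0:
        raise ValueError("descriptive_stats requires at least one value")
    if np.isnan(a).any():
        raise ValueError("descriptive_stats: NaN in input")
    a = np.sort(a)  # makes every statistic exactly order-invariant
    return SummaryStats(
        n=int(a.size),
        mean=float(a.mean()),
        sd=float(a.std(ddof=1)) if a.size >= 2 else None,
        min=float(a.min()),
        q1=float(np.percentile(a, 25)),
        median=float(np.median(a)),
        q3=float(np.percentile(a, 75)),
        max=float(a.max()),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, average ranks on ties)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def summarize_groups(
    breakdowns: Sequence[EvaluationBreakdown], groups: dict[str, str]
) -> dict[str, SummaryStats]:
    """Per-group summary of final scores; key '' covers ungrouped cohorts."""
    by_group: dict[str, list[float]] = {}
    for b in breakdowns:
        g = groups.get(b.participant_id, "")
        by_group.setdefault(g, []).append(b.final_score)
    return {g: descriptive_stats(v) for g, v in sorted(by_group.items())}


def format_summary(summaries: dict[str, SummaryStats]) -> str:
    lines = ["group,n,mean,sd,min,q1,median,q3,max"]
    for g, s in summaries.items():
        sd = "" if s.sd is None else f"{s.sd:.8f}"
        lines.append(
            f"{g or 'all'},{s.n},{s.mean:.8f},{sd},{s.min:.8f},"
            f"{s.q1:.8f},{s.median:.8f},{s.q3:.8f},{s.max:.8f}"
        )
    return "\n".join(lines) + "\n"


def load_reference_outcomes(group: int) -> list[float]:
    """Bundled per-participant final scores reported for the three study groups.

    ``group`` is 1 (deaf soccer players, n=28), 2 (hearing soccer players,
    n=19) or 3 (deaf untrained, n=46).  These are the published outcome
    values, shipped for validating the descriptive statistics; the raw
    dynamometer measurements behind them were never deposited.
    """
    if group not in (1, 2, 3):
        raise ValueError("group must be 1, 2 or 3")
    ref = resources.files("isofuzz.data") / f"reference_outcomes_group{group}.csv"
    with ref.open() as fh:
        df = pd.read_csv(fh)
    return [float(v) for v in df["final_score"]]
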