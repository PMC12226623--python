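"""MADRS series, responder definitions, and cohort exclusion filters.

The Montgomery–Åsberg Depression Rating Scale (MADRS, total 0–60) is
collected at baseline, the day after dosing, and weeks 1, 3, 6, 9 and 12.
A *responder* has a week-3 score reduced by at least 50% of baseline
(boundary inclusive); a *sustained responder* meets the 50% criterion at
every one of weeks 3, 6, 9 and 12.

The exclusion filters mirror the analysis cohort construction: participants
missing the week-3 score are dropped, as are participants whose baseline is
already in the normal range (default cutoff ≤ 6); the sustained analysis
additionally requires weeks 6, 9 and 12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import math

import pandas as pd

#: Assessment weeks; 0 denotes the day-after-dosing assessment.
WEEKS = (0, 1, 3, 6, 9, 12)
SUSTAINED_WEEKS = (3, 6, 9, 12)

_WEEK_COLS = {0: "day1", 1: "w1", 3: "w3", 6: "w6", 9: "w9", 12: "w12"}


class OutcomeError(ValueError):
    pass


@dataclass(frozen=True)
class MADRSSeries:
    participant_id: str
    baseline: int
    scores_by_week: dict[int, int] = field(default_factory=dict)
    dose_mg: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.baseline <= 60):
            raise OutcomeError(
                f"{self.participant_id}: baseline {self.baseline} outside [0, 60]"
            )
        for week, score in self.scores_by_week.items():
            if week not in WEEKS:
                raise OutcomeError(f"{self.participant_id}: unknown week {week}")
            if not (0 <= score <= 60):
                raise OutcomeError(
                    f"{self.participant_id}: week-{week} score {score} outside [0, 60]"
                )

    def has_week(self, week: int) -> bool:
        return week in self.scores_by_week


@dataclass(frozen=True)
class OutcomeLabels:
    responder_week3: Optional[bool]
    sustained_responder: Optional[bool]


def madrs_change(series: MADRSSeries, week: int) -> int:
    """Score at ``week`` minus baseline; negative means improvement."""
    if not series.has_week(week):
        raise OutcomeError(f"{series.participant_id}: missing MADRS at week {week}")
    return series.scores_by_week[week] - series.baseline


def _meets_criterion(series: MADRSSeries, week: int) -> bool:
    # ≥50% reduction, boundary inclusive: score ≤ baseline/2
    return 2 * series.scores_by_week[week] <= series.baseline


def responder_week3(series: MADRSSeries) -> Optional[bool]:
    """True iff the week-3 score is at most half the baseline; None if missing."""
    if series.baseline <= 0:
        raise OutcomeError(f"{series.participant_id}: baseline must be positive")
    if not series.has_week(3):
        return None
    return _meets_criterion(series, 3)


def sustained_responder(series: MADRSSeries) -> Optional[bool]:
    """True iff the 50% criterion holds at weeks 3, 6, 9 and 12; None if any missing."""
    if any(not series.has_week(w) for w in SUSTAINED_WEEKS):
        return None
    return all(_meets_criterion(series, w) for w in SUSTAINED_WEEKS)


def labels(series: MADRSSeries) -> OutcomeLabels:
    return OutcomeLabels(responder_week3(series), sustained_responder(series))


def apply_exclusions(
    cohort: Sequence[MADRSSeries],
    normal_range_max: int = 6,
    sustained: bool = False,
) -> tuple[list[MADRSSeries], pd.DataFrame]:
    """Drop participants unusable for the responder analyses.

    Returns the retained cohort and an exclusion log (participant_id,
    reason).  The week-3 filter drops missing-week-3 and normal-range
    baselines; ``sustained=True`` additionally requires weeks 6, 9 and 12.
    """
    if not cohort:
        raise OutcomeError("empty cohort")
    retained: list[MADRSSeries] = []
    log_rows: list[dict[str, str]] = []
    for series in cohort:
        if not series.has_week(3):
            log_rows.append(
                {"participant_id": series.participant_id, "reason": "missing week-3 MADRS"}
            )
            continue
        if series.baseline <= normal_range_max:
            log_rows.append(
                {
                    "participant_id": series.participant_id,
                    "reason": f"baseline MADRS {series.baseline} in normal range "
                    f"(≤ {normal_range_max})",
                }
            )
            continue
        if sustained and any(not series.has_week(w) for w in (6, 9, 12)):
            missing = [w for w in (6, 9, 12) if not series.has_week(w)]
            log_rows.append(
                {
                    "participant_id": series.participant_id,
                    "reason": f"missing MADRS at week(s) {missing}",
                }
            )
            continue
        retained.append(series)
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    return retained, log


def read_madrs_csv(path: str | Path) -> list[MADRSSeries]:
    """Read series from CSV: participant_id, baseline, day1, w1, w3, w6, w9,
    w12, dose_mg; missing cells empty."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = ["participant_id", "baseline"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise OutcomeError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        scores = {}
        for week, col in _WEEK_COLS.items():
            if col in df.columns and not (
                row[col] is None or (isinstance(row[col], float) and math.isnan(row[col]))
            ):
                scores[week] = int(row[col])
        dose = None
        if "dose_mg" in df.columns and not pd.isna(row["dose_mg"]):
            dose = int(row["dose_mg"])
        out.append(
            MADRSSeries(
                participant_id=row["participant_id"],
                baseline=int(row["baseline"]),
                scores_by_week=scores,
                dose_mg=dose,
            )
        )
    return out


def write_madrs_csv(cohort: Iterable[MADRSSeries], path: str | Path) -> None:
    rows = []
    for s in cohort:
        row: dict[str, object] = {
            "participant_id": s.participant_id,
            "baseline": s.baseline,
        }
        for week, col in _WEEK_COLS.items():
            row[col] = s.scores_by_week.get(week, "")
        row["dose_mg"] = s.dose_mg if s.dose_mg is not None else ""
        rows.append(row)
    cols = ["participant_id", "baseline", *_WEEK_COLS.values(), "dose_mg"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
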