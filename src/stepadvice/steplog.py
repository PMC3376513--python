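"""Pedometer step-log processing.

Participants wear a waist-worn pedometer (Yamax Digiwalker SW-200 protocol)
for 7 consecutive days and record, per day, the steps taken plus the kind and
duration of non-ambulatory activities such as biking and swimming. This module
turns those logs into a single steps/day level:

1. credit 150 steps per minute of each convertible activity,
2. truncate the adjusted daily total at 20,000 steps/day,
3. average over valid days, requiring at least 5 of them.

The resulting :class:`StepSummary` is what both the tailoring engine and the
trial-statistics layer consume.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .config import (
    DEFAULT_CAP,
    DEFAULT_CONVERSION_RATE,
    DEFAULT_CONVERTIBLE_ACTIVITIES,
    DEFAULT_GOAL,
    DEFAULT_MIN_VALID_DAYS,
)
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "Activity",
    "DailyRecord",
    "StepLog",
    "StepSummary",
    "adjust_daily_steps",
    "truncate_daily",
    "summarize_log",
    "meets_step_goal",
    "read_steplog_csv",
    "write_steplog_csv",
]


@dataclass(frozen=True)
class Activity:
    """A non-ambulatory activity entry: kind label + duration in minutes."""

    kind: str
    minutes: float

    def __post_init__(self):
        if self.minutes < 0:
            raise ValidationError(
                f"activity '{self.kind}': negative duration {self.minutes}"
            )


@dataclass(frozen=True)
class DailyRecord:
    """One day of the log.

    ``steps`` may be ``None`` for a day the participant did not register;
    such days are invalid and excluded from the average. A recorded 0 is a
    valid (sedentary or device-off) day.
    """

    date: Date
    steps: Optional[int]
    activities: tuple[Activity, ...] = ()

    def __post_init__(self):
        if self.steps is not None and self.steps < 0:
            raise ValidationError(f"{self.date}: negative step count {self.steps}")

    @property
    def is_valid(self) -> bool:
        return self.steps is not None


@dataclass(frozen=True)
class StepLog:
    """An ordered, duplicate-free sequence of daily records for one participant."""

    participant_id: str
    records: tuple[DailyRecord, ...]

    def __post_init__(self):
        ordered = tuple(sorted(self.records, key=lambda r: r.date))
        dates = [r.date for r in ordered]
        if len(set(dates)) != len(dates):
            dupes = sorted({d for d in dates if dates.count(d) > 1})
            raise ValidationError(
                f"step log '{self.participant_id}': duplicate dates {dupes}"
            )
        object.__setattr__(self, "records", ordered)


@dataclass(frozen=True)
class StepSummary:
    """Average adjusted-and-capped steps/day over the valid days of a log."""

    mean_steps_per_day: float
    n_valid_days: int
    any_truncated: bool


def adjust_daily_steps(
    record: DailyRecord,
    conversion_rate: float = DEFAULT_CONVERSION_RATE,
    convertible: Sequence[str] = DEFAULT_CONVERTIBLE_ACTIVITIES,
) -> float:
    """Credit ``conversion_rate`` steps per minute of each convertible activity.

    Activities outside ``convertible`` (by default biking and swimming)
    contribute nothing.
    """
    if conversion_rate < 0:
        raise ValidationError("conversion_rate must be >= 0")
    if record.steps is None:
        raise ValidationError(f"{record.date}: no step count recorded")
    convertible_set = {k.lower() for k in convertible}
    extra = sum(
        a.minutes for a in record.activities if a.kind.lower() in convertible_set
    )
    return record.steps + conversion_rate * extra


def truncate_daily(steps: float, cap: float = DEFAULT_CAP) -> float:
    """Cap a daily total; idempotent and monotone in ``steps``."""
    if steps < 0:
        raise ValidationError(f"negative step count {steps}")
    if cap <= 0:
        raise ValidationError("cap must be positive")
    return min(steps, cap)


def summarize_log(
    log: StepLog,
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
    cap: float = DEFAULT_CAP,
    conversion_rate: float = DEFAULT_CONVERSION_RATE,
    convertible: Sequence[str] = DEFAULT_CONVERTIBLE_ACTIVITIES,
) -> StepSummary:
    """Adjust, truncate, and average a log over its valid days.

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_valid_days`` days carry a step count.
    """
    if min_valid_days < 1:
        raise ValidationError("min_valid_days must be >= 1")
    valid = [r for r in log.records if r.is_valid]
    if len(valid) < min_valid_days:
        raise InsufficientDataError(log.participant_id, len(valid), min_valid_days)
    daily = [
        truncate_daily(
            adjust_daily_steps(r, conversion_rate, convertible), cap
        )
        for r in valid
    ]
    any_truncated = any(
        adjust_daily_steps(r, conversion_rate, convertible) > cap for r in valid
    )
    return StepSummary(
        mean_steps_per_day=sum(daily) / len(daily),
        n_valid_days=len(daily),
        any_truncated=any_truncated,
    )


def meets_step_goal(summary: StepSummary, goal: float = DEFAULT_GOAL) -> bool:
    """True iff the average reaches the goal (boundary inclusive)."""
    if goal <= 0:
        raise ValidationError("goal must be positive")
    return summary.mean_steps_per_day >= goal


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: header `date,steps,activity,activity_minutes`; ISO-8601 dates; one
# row per day; extra rows repeating a date with a nonempty `activity` attach
# further activities to that day.
# ---------------------------------------------------------------------------

_HEADER = ("date", "steps", "activity", "activity_minutes")


def read_steplog_csv(path: str | Path, participant_id: Optional[str] = None) -> StepLog:
    """Parse a step-log CSV into a :class:`StepLog`."""
    path = Path(path)
    pid = participant_id or path.stem
    days: dict[Date, Optional[int]] = {}
    acts: dict[Date, list[Activity]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_HEADER) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"{path}: missing CSV columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                day = datetime.strptime(row["date"].strip(), "%Y-%m-%d").date()
            except ValueError as exc:
                raise ValidationError(f"{path}:{i}: bad date {row['date']!r}") from exc
            steps_raw = (row["steps"] or "").strip()
            activity = (row["activity"] or "").strip()
            if day in days:
                if not activity:
                    raise ValidationError(
                        f"{path}:{i}: duplicate date {day} without an activity"
                    )
            else:
                days[day] = int(steps_raw) if steps_raw else None
                acts[day] = []
            if activity:
                minutes_raw = (row["activity_minutes"] or "").strip()
                if not minutes_raw:
                    raise ValidationError(
                        f"{path}:{i}: activity '{activity}' has no duration"
                    )
                acts[day].append(Activity(kind=activity, minutes=float(minutes_raw)))
    records = tuple(
        DailyRecord(date=d, steps=days[d], activities=tuple(acts[d]))
        for d in sorted(days)
    )
    return StepLog(participant_id=pid, records=records)


def write_steplog_csv(log: StepLog, path: str | Path) -> None:
    """Write a :class:`StepLog` in the CSV dialect :func:`read_steplog_csv` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for rec in log.records:
            steps = "" if rec.steps is None else rec.steps
            if rec.activities:
                first, *rest = rec.activities
                writer.writerow(
                    [rec.date.isoformat(), steps, first.kind, _fmt_min(first.minutes)]
                )
                for act in rest:
                    writer.writerow(
                        [rec.date.isoformat(), "", act.kind, _fmt_min(act.minutes)]
                    )
            else:
                writer.writerow([rec.date.isoformat(), steps, "", ""])


def _fmt_min(minutes: float) -> str:
    return str(int(minutes)) if float(minutes).is_integer() else str(minutes)
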