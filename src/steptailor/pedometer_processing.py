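"""Pedometer data reduction.

Daily step records from a 7-day-memory pedometer are validated, truncated
and averaged into the single average-daily-steps quantity used both for
tailoring advice and as the trial outcome.  The rules:

* a day is valid when the device registered more than 100 steps and was
  worn at least 8 hours;
* daily counts above 20,000 steps are truncated to 20,000 before averaging;
* the average requires at least 5 *consecutive* calendar days of valid
  wear, optionally containing at least one weekend day.

Wear time is not recorded by the device; it is reconstructed from the
participant's activity log as 24 h minus a sleep window (default 8 h)
minus logged non-wear periods.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

MIN_DAILY_STEPS = 100  # strictly more than this counts as a worn day
MIN_WEAR_HOURS = 8.0
TRUNCATION_CAP = 20_000
MIN_CONSECUTIVE_DAYS = 5
DEFAULT_SLEEP_HOURS = 8.0
MAX_DAYS_PER_WAVE = 7  # the device memory holds one week


@dataclass(frozen=True)
class DailyStepRecord:
    participant_id: str
    date: dt.date
    steps: int
    wear_hours: float
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be nonnegative")
        if not 0 <= self.wear_hours <= 24:
            raise ValueError("wear_hours must lie in [0, 24]")


@dataclass(frozen=True)
class StepSeries:
    """One participant's records for one measurement wave (at most 7 days)."""

    records: tuple[DailyStepRecord, ...]

    def __post_init__(self) -> None:
        dates = [r.date for r in self.records]
        if len(set(dates)) != len(dates):
            raise ValueError("duplicate dates in step series")
        if len(dates) > MAX_DAYS_PER_WAVE:
            raise ValueError(
                f"a wave holds at most {MAX_DAYS_PER_WAVE} daily records"
            )
        object.__setattr__(
            self, "records", tuple(sorted(self.records, key=lambda r: r.date))
        )

    @classmethod
    def from_records(cls, records: Iterable[DailyStepRecord]) -> "StepSeries":
        return cls(tuple(records))


@dataclass(frozen=True)
class ActivityLogEntry:
    """One activity-log line: a non-wear period or a non-walking activity."""

    date: dt.date
    hours: float
    kind: str = "nonwear"  # "nonwear" or an activity label, e.g. "swimming"

    def __post_init__(self) -> None:
        if self.hours < 0:
            raise ValueError("logged hours must be nonnegative")


@dataclass(frozen=True)
class StepAverage:
    """Result of averaging one wave: a value or an invalid-marker."""

    value: Optional[float]
    n_days: int
    reason: Optional[str] = None  # set iff invalid

    @property
    def valid(self) -> bool:
        return self.value is not None


def is_valid_day(record: DailyStepRecord) -> bool:
    """True iff the day passes the wear-time validity rule."""
    return record.steps > MIN_DAILY_STEPS and record.wear_hours >= MIN_WEAR_HOURS


def truncate_steps(steps: float) -> float:
    """Cap a daily count at 20,000 steps to avoid unrealistically high data."""
    if steps < 0:
        raise ValueError("steps must be nonnegative")
    return min(steps, TRUNCATION_CAP)


def _runs_of_consecutive_valid_days(
    records: Sequence[DailyStepRecord],
) -> list[list[DailyStepRecord]]:
    runs: list[list[DailyStepRecord]] = []
    current: list[DailyStepRecord] = []
    for rec in records:
        if not is_valid_day(rec):
            if current:
                runs.append(current)
            current = []
            continue
        if current and (rec.date - current[-1].date).days != 1:
            runs.append(current)
            current = []
        current.append(rec)
    if current:
        runs.append(current)
    return runs


def average_daily_steps(series: StepSeries,
                        require_weekend: bool = True) -> StepAverage:
    """Average truncated daily steps over the longest valid consecutive run.

    A run is a stretch of consecutive calendar dates whose records all pass
    :func:`is_valid_day`; a single invalid or missing day breaks it.  The
    average is returned only for a run of at least 5 days that (when
    ``require_weekend``) contains a Saturday or Sunday; otherwise an
    invalid-marker with a reason code comes back.
    """
    if not series.records:
        return StepAverage(value=None, n_days=0, reason="empty")
    runs = _runs_of_consecutive_valid_days(series.records)
    long_enough = [r for r in runs if len(r) >= MIN_CONSECUTIVE_DAYS]
    if not long_enough:
        return StepAverage(value=None,
                           n_days=max((len(r) for r in runs), default=0),
                           reason="too_few_consecutive")
    if require_weekend:
        eligible = [r for r in long_enough
                    if any(rec.date.weekday() >= 5 for rec in r)]
        if not eligible:
            return StepAverage(value=None,
                               n_days=max(len(r) for r in long_enough),
                               reason="no_weekend_day")
    else:
        eligible = long_enough
    best = max(eligible, key=len)  # ties resolve to the earliest run
    mean = sum(truncate_steps(rec.steps) for rec in best) / len(best)
    return StepAverage(value=mean, n_days=len(best))


def merge_activity_log(series: StepSeries,
                       log: Sequence[ActivityLogEntry],
                       sleep_hours: float = DEFAULT_SLEEP_HOURS) -> StepSeries:
    """Reconstruct wear hours from the activity log.

    Per day: ``wear = 24 - sleep_hours - logged non-wear hours``, floored at
    0.  Non-walking activities (swimming, cycling, ...) become annotations
    on the day's record, not steps.  A log entry dated outside the series
    raises, since it cannot be reconciled.
    """
    if not 0 <= sleep_hours <= 24:
        raise ValueError("sleep_hours must lie in [0, 24]")
    by_date = {rec.date: rec for rec in series.records}
    for entry in log:
        if entry.date not in by_date:
            raise ValueError(
                f"activity-log date {entry.date} not in the measured week"
            )
    if not log:
        return series
    nonwear: dict[dt.date, float] = {}
    notes: dict[dt.date, list[str]] = {}
    for entry in log:
        if entry.kind == "nonwear":
            nonwear[entry.date] = nonwear.get(entry.date, 0.0) + entry.hours
        else:
            notes.setdefault(entry.date, []).append(entry.kind)
    new_records = []
    for rec in series.records:
        wear = max(0.0, min(24.0, 24.0 - sleep_hours - nonwear.get(rec.date, 0.0)))
        new_records.append(replace(
            rec,
            wear_hours=wear,
            annotations=rec.annotations + tuple(notes.get(rec.date, ())),
        ))
    return StepSeries(tuple(new_records))


def read_step_log(path) -> pd.DataFrame:
    """Read a step-log CSV: participant_id, wave, date, steps[, wear_hours]."""
    df = pd.read_csv(path, dtype={"participant_id": str, "wave": str})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if "wear_hours" not in df.columns:
        df["wear_hours"] = 24.0 - DEFAULT_SLEEP_HOURS
    return df


def summarize_participants(step_log: pd.DataFrame,
                           require_weekend: bool = True) -> pd.DataFrame:
    """Per participant x wave QC summary: avg_steps, n_valid_days, validity."""
    rows = []
    for (pid, wave), grp in step_log.groupby(["participant_id", "wave"],
                                             sort=True):
        series = StepSeries.from_records(
            DailyStepRecord(participant_id=pid, date=row.date,
                            steps=int(row.steps),
                            wear_hours=float(row.wear_hours))
            for row in grp.itertuples()
        )
        avg = average_daily_steps(series, require_weekend=require_weekend)
        rows.append({
            "participant_id": pid,
            "wave": wave,
            "avg_steps": avg.value,
            "n_valid_days": avg.n_days,
            "valid": avg.valid,
            "reason": avg.reason or "",
        })
    return pd.DataFrame(rows)
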