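"""Caregiver sleep-diary records and diary-derived sleep parameters.

A diary record holds one night's caregiver entries: bedtime, wake-up
time, sleep-onset latency, the number of awakenings the caregiver
noticed (episodes longer than roughly five minutes), plus lifestyle
fields (nap, screen, outdoor, bath, dinner times) that are carried
through verbatim but not analysed.

Diary night-time sleep is defined as the bed-to-wake span minus the
reported latency.  Cross-midnight spans are handled by anchoring every
night to its bedtime's calendar date and unrolling clock times onto a
minutes-since-noon axis (see :mod:`actisleep.timeutil`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from datetime import date, datetime, time

import pandas as pd

from .errors import ValidationError
from .timeutil import is_weekend_night, minutes_since_noon, parse_clock, unroll

DIARY_CSV_COLUMNS = (
    "child_id", "night_date", "bedtime", "wake_date", "wake_up",
    "sleep_latency_min", "reported_awakenings", "nap_start", "nap_end",
    "screen_time_min", "outdoor_time_min", "bath_time", "dinner_time",
    "prebed_activity", "caregiver_bed", "caregiver_wake", "stress_level",
)


@dataclass
class DiaryRecord:
    """One night of caregiver app entries for one child."""

    child_id: str
    night_date: date
    bedtime: time
    wake_up: time
    sleep_latency_min: int
    reported_awakenings: int
    wake_date: date | None = None  # inferred (noon rule) when absent
    nap_start: time | None = None
    nap_end: time | None = None
    screen_time_min: int | None = None
    outdoor_time_min: int | None = None
    bath_time: time | None = None
    dinner_time: time | None = None
    prebed_activity: str | None = None
    caregiver_bed: time | None = None
    caregiver_wake: time | None = None
    stress_level: int | None = None

    def __post_init__(self) -> None:
        if self.sleep_latency_min < 0:
            raise ValidationError("sleep_latency_min must be >= 0")
        if self.reported_awakenings < 0:
            raise ValidationError("reported_awakenings must be >= 0")
        if self.wake_datetime() <= self.bed_datetime():
            raise ValidationError(
                f"wake-up does not follow bedtime for child {self.child_id!r} "
                f"night {self.night_date.isoformat()}"
            )

    def bed_datetime(self) -> datetime:
        return unroll(self.bedtime, self.night_date)

    def wake_datetime(self) -> datetime:
        if self.wake_date is not None:
            return datetime.combine(self.wake_date, self.wake_up)
        return unroll(self.wake_up, self.night_date)


@dataclass
class SleepSummary:
    """One night's four headline sleep measures from one source.

    ``source`` is "actigraphy" or "diary".  ``bedtime`` for actigraphy
    summaries is the detected sleep onset (a documented proxy: the
    device cannot see in-bed wakefulness as bedtime).
    """

    child_id: str
    night_date: date
    source: str
    bedtime: datetime
    wake_up: datetime
    nighttime_sleep: float  # minutes
    awakenings: float
    is_weekend: bool
    month: int | None = None

    def __post_init__(self) -> None:
        if self.source not in ("actigraphy", "diary"):
            raise ValidationError(f"unknown source {self.source!r}")
        span = (self.wake_up - self.bedtime).total_seconds() / 60.0
        if not (0 <= self.nighttime_sleep <= span + 1e-9):
            raise ValidationError(
                "nighttime_sleep must lie within the bed-to-wake span"
            )

    def bedtime_minutes(self) -> float:
        """Bedtime on the night's minutes-since-noon axis."""
        return minutes_since_noon(self.bedtime, self.night_date)

    def wake_up_minutes(self) -> float:
        return minutes_since_noon(self.wake_up, self.night_date)


def diary_nighttime_sleep(record: DiaryRecord) -> float:
    """Bed-to-wake span minus reported sleep latency, in minutes."""
    span = (record.wake_datetime() - record.bed_datetime()).total_seconds() / 60.0
    if record.sleep_latency_min > span:
        raise ValidationError(
            f"sleep latency ({record.sleep_latency_min} min) exceeds the "
            f"bed-to-wake span ({span:.0f} min)"
        )
    return span - record.sleep_latency_min


def diary_to_summary(
    record: DiaryRecord,
    weekend_rule=is_weekend_night,
    month: int | None = None,
) -> SleepSummary:
    """Project a diary record onto the common per-night summary shape."""
    missing = [
        name
        for name in ("child_id", "night_date", "bedtime", "wake_up")
        if getattr(record, name) is None
    ]
    if missing:
        raise ValidationError(f"diary record missing mandatory fields: {missing}")
    return SleepSummary(
        child_id=record.child_id,
        night_date=record.night_date,
        source="diary",
        bedtime=record.bed_datetime(),
        wake_up=record.wake_datetime(),
        nighttime_sleep=diary_nighttime_sleep(record),
        awakenings=float(record.reported_awakenings),
        is_weekend=weekend_rule(record.night_date),
        month=month,
    )


def _fmt_time(t: time | None) -> str:
    return "" if t is None else f"{t.hour:02d}:{t.minute:02d}"


def _fmt_opt(v) -> str:
    return "" if v is None else str(v)


def write_diary_csv(records: list[DiaryRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "child_id": r.child_id,
                "night_date": r.night_date.isoformat(),
                "bedtime": _fmt_time(r.bedtime),
                "wake_date": r.wake_datetime().date().isoformat(),
                "wake_up": _fmt_time(r.wake_up),
                "sleep_latency_min": r.sleep_latency_min,
                "reported_awakenings": r.reported_awakenings,
                "nap_start": _fmt_time(r.nap_start),
                "nap_end": _fmt_time(r.nap_end),
                "screen_time_min": _fmt_opt(r.screen_time_min),
                "outdoor_time_min": _fmt_opt(r.outdoor_time_min),
                "bath_time": _fmt_time(r.bath_time),
                "dinner_time": _fmt_time(r.dinner_time),
                "prebed_activity": _fmt_opt(r.prebed_activity),
                "caregiver_bed": _fmt_time(r.caregiver_bed),
                "caregiver_wake": _fmt_time(r.caregiver_wake),
                "stress_level": _fmt_opt(r.stress_level),
            }
        )
    pd.DataFrame(rows, columns=list(DIARY_CSV_COLUMNS)).to_csv(path, index=False)


def _parse_opt_time(value, row_no: int, column: str) -> time | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return parse_clock(str(value))
    except ValueError as exc:
        raise ValidationError(f"row {row_no}, column {column!r}: {exc}") from exc


def _parse_opt_int(value, row_no: int, column: str) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return int(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"row {row_no}, column {column!r}: not an integer") from exc


def read_diary_csv(path) -> list[DiaryRecord]:
    """Read diary records from a strict-schema CSV; errors name the row."""
    df = pd.read_csv(path, dtype={"prebed_activity": str})
    if tuple(df.columns) != DIARY_CSV_COLUMNS:
        raise ValidationError(
            f"diary CSV must have columns {DIARY_CSV_COLUMNS}, got {tuple(df.columns)}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = row._asdict()
        try:
            night = date.fromisoformat(str(d["night_date"]))
            wake_date = (
                date.fromisoformat(str(d["wake_date"])) if _present(d["wake_date"]) else None
            )
            record = DiaryRecord(
                child_id=str(d["child_id"]),
                night_date=night,
                bedtime=_require_time(d["bedtime"], i, "bedtime"),
                wake_up=_require_time(d["wake_up"], i, "wake_up"),
                wake_date=wake_date,
                sleep_latency_min=int(d["sleep_latency_min"]),
                reported_awakenings=int(d["reported_awakenings"]),
                nap_start=_parse_opt_time(d["nap_start"], i, "nap_start"),
                nap_end=_parse_opt_time(d["nap_end"], i, "nap_end"),
                screen_time_min=_parse_opt_int(d["screen_time_min"], i, "screen_time_min"),
                outdoor_time_min=_parse_opt_int(d["outdoor_time_min"], i, "outdoor_time_min"),
                bath_time=_parse_opt_time(d["bath_time"], i, "bath_time"),
                dinner_time=_parse_opt_time(d["dinner_time"], i, "dinner_time"),
                prebed_activity=(str(d["prebed_activity"]) if _present(d["prebed_activity"]) else None),
                caregiver_bed=_parse_opt_time(d["caregiver_bed"], i, "caregiver_bed"),
                caregiver_wake=_parse_opt_time(d["caregiver_wake"], i, "caregiver_wake"),
                stress_level=_parse_opt_int(d["stress_level"], i, "stress_level"),
            )
        except ValidationError:
            raise
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        records.append(record)
    return records


def _present(value) -> bool:
    return not (
        value is None
        or (isinstance(value, float) and math.isnan(value))
        or value == ""
    )


def _require_time(value, row_no: int, column: str) -> time:
    t = _parse_opt_time(value, row_no, column)
    if t is None:
        raise ValidationError(f"row {row_no}: mandatory column {column!r} is empty")
    return t
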