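"""Clock-time arithmetic on the minutes-since-noon axis.

Night-time events straddle midnight, so naive clock averages are wrong
(mean of 23:50 and 00:10 must be 00:00, not 12:00).  Every clock quantity
belonging to a night is mapped onto a single monotone axis: minutes since
noon of the night's calendar date.  Bedtimes land around 540 (21:00),
wake-ups around 1110 (06:30 next day), and spans are plain differences.
A night is keyed to the calendar date of its bedtime.
"""

from __future__ import annotations

from datetime import date, datetime, time, timedelta

NOON_MINUTES = 12 * 60


def noon_of(day: date) -> datetime:
    return datetime(day.year, day.month, day.day, 12, 0)


def minutes_since_noon(moment: datetime, night_date: date) -> float:
    """Minutes from noon of ``night_date`` to ``moment`` (may exceed 1440)."""
    return (moment - noon_of(night_date)).total_seconds() / 60.0


def clock_minutes_since_noon(t: time) -> float:
    """Map a bare clock time onto [0, 1440) minutes past noon.

    Times from 12:00 onward belong to the night's own evening; times
    before 12:00 are taken as the following morning.
    """
    m = t.hour * 60 + t.minute + t.second / 60.0
    return (m - NOON_MINUTES) % (24 * 60)


def unroll(t: time, night_date: date) -> datetime:
    """Place a clock time on the night anchored at ``night_date``."""
    return noon_of(night_date) + timedelta(minutes=clock_minutes_since_noon(t))


def minutes_to_clock(minutes: float) -> str:
    """Format minutes-since-noon back to HH:MM wall-clock."""
    total = (minutes + NOON_MINUTES) % (24 * 60)
    h, m = divmod(int(round(total)), 60)
    if m == 60:  # guard rounding at :59.5+
        h, m = h + 1, 0
    return f"{h % 24:02d}:{m:02d}"


def parse_clock(text: str) -> time:
    """Parse strict HH:MM (24-hour); raise ValueError otherwise."""
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"not an HH:MM time: {text!r}")
    h, m = int(parts[0]), int(parts[1])
    if not (0 <= h <= 23 and 0 <= m <= 59):
        raise ValueError(f"clock time out of range: {text!r}")
    return time(h, m)


def is_weekend_night(night_date: date) -> bool:
    """Default weekend rule: the bedtime's date is a Saturday or Sunday."""
    return night_date.weekday() >= 5
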