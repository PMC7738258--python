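"""Sleep/wake scoring of 2-minute activity-intensity epochs.

An epoch is scored from a five-epoch sliding window (the epoch itself
plus two before and two after, 10 minutes total) with a weighted linear
score

    z = 0.24669 x[-2] + 0.2562 x[-1] + 0.408771 x + 0.155046 x[+1] + 0.136728 x[+2]

and labelled wake when z >= 1, sleep when z < 1.  On top of the labels
this module extracts maximal wake runs ("awakenings", counted when they
last 6 minutes = 3 epochs or more), detects sleep onset and final
morning waking inside a night window via a sustained-sleep-run rule, and
sums night-time sleep as sleep-labelled time between onset and offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np

from .actigraph import EPOCH_MINUTES, MAX_INTENSITY, ActivityIntensitySeries
from .diary import SleepSummary
from .errors import NoSleepError, ValidationError
from .timeutil import is_weekend_night

SLEEP, WAKE, UNDEFINED = 0, 1, -1
LABEL_NAMES = {SLEEP: "sleep", WAKE: "wake", UNDEFINED: "undefined"}

DEFAULT_SUSTAINED_EPOCHS = 5  # 10 min of continuous sleep marks onset/offset
DEFAULT_MIN_AWAKENING_MIN = 6


@dataclass(frozen=True)
class ClassifierWeights:
    """The five window coefficients and the wake threshold on z."""

    a_m2: float = 0.24669
    a_m1: float = 0.2562
    a_0: float = 0.408771
    a_p1: float = 0.155046
    a_p2: float = 0.136728
    wake_threshold: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.a_m2, self.a_m1, self.a_0, self.a_p1, self.a_p2])


DEFAULT_WEIGHTS = ClassifierWeights()


@dataclass
class SleepWakeSeries:
    """Per-epoch z scores and sleep/wake labels aligned to a source series.

    Boundary epochs (the first and last two) have no full window; under
    the default boundary mode their z is NaN and their label UNDEFINED.
    """

    child_id: str
    start_time: datetime
    z_scores: np.ndarray
    labels: np.ndarray
    epoch_length_min: int = EPOCH_MINUTES

    def __len__(self) -> int:
        return int(self.labels.size)

    def epoch_start(self, index: int) -> datetime:
        return self.start_time + timedelta(minutes=self.epoch_length_min * index)

    def index_at(self, moment: datetime) -> int:
        """Index of the epoch containing ``moment`` (clamped to range)."""
        offset = (moment - self.start_time).total_seconds() / 60.0
        return int(np.clip(offset // self.epoch_length_min, 0, len(self) - 1))


@dataclass(frozen=True)
class WakeEvent:
    """A maximal run of wake-labelled epochs."""

    start_epoch: int
    end_epoch: int  # exclusive

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch

    @property
    def duration_min(self) -> int:
        return EPOCH_MINUTES * self.n_epochs


@dataclass(frozen=True)
class NightWindow:
    """The analysis frame for one night, keyed to its bedtime's date."""

    night_date: date
    window_start: datetime
    window_end: datetime

    def __post_init__(self) -> None:
        if self.window_end <= self.window_start:
            raise ValidationError("window_end must be after window_start")
        if self.window_end - self.window_start > timedelta(hours=24):
            raise ValidationError("a night window spans at most 24 h")


@dataclass(frozen=True)
class SleepPeriod:
    """Detected sleep onset and final morning waking for one night."""

    onset_epoch: int
    final_wake_epoch: int  # exclusive: first epoch after the last sleep epoch
    sleep_onset: datetime
    final_wake: datetime


def score_epoch(
    x_m2: int, x_m1: int, x: int, x_p1: int, x_p2: int,
    weights: ClassifierWeights = DEFAULT_WEIGHTS,
) -> tuple[float, str]:
    """Score one epoch from its five-intensity window; return (z, label)."""
    xs = np.array([x_m2, x_m1, x, x_p1, x_p2], dtype=float)
    if np.any((xs < 0) | (xs > MAX_INTENSITY)):
        raise ValidationError(f"intensities must lie in [0, {MAX_INTENSITY}]")
    z = float(xs @ weights.as_array())
    label = WAKE if z >= weights.wake_threshold else SLEEP
    return z, LABEL_NAMES[label]


def classify_series(
    series: ActivityIntensitySeries,
    weights: ClassifierWeights = DEFAULT_WEIGHTS,
    boundary_mode: str = "undefined",
) -> SleepWakeSeries:
    """Label every epoch of an intensity series.

    boundary_mode
        "undefined": the first/last two epochs get NaN z and the
        UNDEFINED label (no data is fabricated);
        "pad": the series is edge-padded by replicating its first and
        last intensity so every epoch gets a defined score.
    """
    if boundary_mode not in ("undefined", "pad"):
        raise ValidationError(f"unknown boundary_mode {boundary_mode!r}")
    x = series.intensities.astype(float)
    n = x.size
    w = weights.as_array()
    z = np.full(n, np.nan)
    labels = np.full(n, UNDEFINED, dtype=np.int8)
    if boundary_mode == "pad":
        xp = np.pad(x, 2, mode="edge")
        z[:] = np.correlate(xp, w, mode="valid")
    elif n >= 5:
        z[2 : n - 2] = np.correlate(x, w, mode="valid")
    defined = ~np.isnan(z)
    labels[defined & (z >= weights.wake_threshold)] = WAKE
    labels[defined & (z < weights.wake_threshold)] = SLEEP
    return SleepWakeSeries(
        child_id=series.child_id,
        start_time=series.start_time,
        z_scores=z,
        labels=labels,
    )


def _runs(labels: np.ndarray, value: int) -> list[tuple[int, int]]:
    """Maximal runs of ``value`` as (start, stop) index pairs, stop exclusive."""
    mask = labels == value
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def extract_wake_events(
    sw: SleepWakeSeries,
    min_duration_min: int = DEFAULT_MIN_AWAKENING_MIN,
    *,
    start_epoch: int = 0,
    end_epoch: int | None = None,
    undefined_policy: str = "error",
) -> list[WakeEvent]:
    """Maximal wake runs of at least ``min_duration_min`` within a span.

    ``undefined_policy`` controls epochs without a defined label inside
    the span: "error" (default) refuses to count, "sleep"/"wake" recode
    them before the scan.  A run is clipped at the span boundaries, so a
    wake run straddling the span counts only its inside portion.
    """
    end_epoch = len(sw) if end_epoch is None else end_epoch
    if not (0 <= start_epoch <= end_epoch <= len(sw)):
        raise ValidationError("span out of range")
    labels = sw.labels[start_epoch:end_epoch].copy()
    if (labels == UNDEFINED).any():
        if undefined_policy == "error":
            raise ValidationError(
                "undefined labels inside the analysed span; choose "
                "undefined_policy='sleep' or 'wake' to recode them"
            )
        if undefined_policy not in ("sleep", "wake"):
            raise ValidationError(f"unknown undefined_policy {undefined_policy!r}")
        labels[labels == UNDEFINED] = SLEEP if undefined_policy == "sleep" else WAKE
    min_epochs = int(np.ceil(min_duration_min / EPOCH_MINUTES))
    return [
        WakeEvent(a + start_epoch, b + start_epoch)
        for a, b in _runs(labels, WAKE)
        if b - a >= min_epochs
    ]


def detect_onset_offset(
    sw: SleepWakeSeries,
    night: NightWindow,
    sustained_epochs: int = DEFAULT_SUSTAINED_EPOCHS,
) -> SleepPeriod:
    """Locate sleep onset and the final morning waking inside a night window.

    Onset is the start of the first run of at least ``sustained_epochs``
    consecutive sleep epochs after the window start; the final waking is
    the end of the last such run.  A qualifying run that touches the end
    of the window means sleep continued past the analysed night, which is
    reported as an error rather than a fabricated waking.
    """
    if sustained_epochs < 1:
        raise ValidationError("sustained_epochs must be >= 1")
    if night.window_start < sw.epoch_start(0) or night.window_end > sw.epoch_start(len(sw)):
        raise ValidationError("night window extends beyond the scored series")
    lo = sw.index_at(night.window_start)
    hi = sw.index_at(night.window_end - timedelta(seconds=1)) + 1
    runs = [
        (a + lo, b + lo)
        for a, b in _runs(sw.labels[lo:hi], SLEEP)
        if b - a >= sustained_epochs
    ]
    if not runs:
        raise NoSleepError(
            f"no run of >= {sustained_epochs} sleep epochs in the night of "
            f"{night.night_date.isoformat()} for child {sw.child_id!r}"
        )
    onset_epoch = runs[0][0]
    final_epoch = runs[-1][1]
    if final_epoch >= hi:
        raise NoSleepError(
            f"sleep continues to the end of the window on "
            f"{night.night_date.isoformat()}; no final waking detected"
        )
    return SleepPeriod(
        onset_epoch=onset_epoch,
        final_wake_epoch=final_epoch,
        sleep_onset=sw.epoch_start(onset_epoch),
        final_wake=sw.epoch_start(final_epoch),
    )


def nighttime_sleep_actigraphy(sw: SleepWakeSeries, period: SleepPeriod) -> int:
    """Sleep-labelled minutes between onset and final waking.

    Wake epochs inside the span are excluded, so the result is at most
    the elapsed onset-to-waking span.
    """
    span = sw.labels[period.onset_epoch : period.final_wake_epoch]
    return int((span == SLEEP).sum()) * EPOCH_MINUTES


def summarize_night_actigraphy(
    series: ActivityIntensitySeries,
    night: NightWindow,
    weights: ClassifierWeights = DEFAULT_WEIGHTS,
    *,
    sustained_epochs: int = DEFAULT_SUSTAINED_EPOCHS,
    min_awakening_min: int = DEFAULT_MIN_AWAKENING_MIN,
    boundary_mode: str = "undefined",
    month: int | None = None,
) -> SleepSummary:
    """Score one night end to end and bundle the four headline measures.

    The detected sleep onset stands in for "bedtime": the device sees
    only movement, so in-bed-but-awake time cannot be separated from
    pre-bed wakefulness.
    """
    sw = classify_series(series, weights, boundary_mode)
    period = detect_onset_offset(sw, night, sustained_epochs)
    events = extract_wake_events(
        sw,
        min_awakening_min,
        start_epoch=period.onset_epoch,
        end_epoch=period.final_wake_epoch,
    )
    return SleepSummary(
        child_id=series.child_id,
        night_date=night.night_date,
        source="actigraphy",
        bedtime=period.sleep_onset,
        wake_up=period.final_wake,
        nighttime_sleep=float(nighttime_sleep_actigraphy(sw, period)),
        awakenings=float(len(events)),
        is_weekend=is_weekend_night(night.night_date),
        month=month,
    )
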