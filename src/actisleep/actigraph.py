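"""Accelerometer epoching: raw samples -> 2-minute activity intensities.

The wearable samples acceleration every 0.125 s and, per 2-minute bin
(960 samples), counts how often the magnitude exceeds a reference value
("activity value").  The activity value is then compressed to a 64-level
activity intensity in [0, 63]; 0 means the wearer did not move at all.

The device's activity-value -> intensity mapping is not public.  The
default here is a linear compression ``floor(value / 15)`` clipped to 63,
which spans the full 0-63 range over a fully active window
(960 / 15 = 64); the divisor is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import GapError, ValidationError

SAMPLE_PERIOD_S = 0.125
EPOCH_MINUTES = 2
SAMPLES_PER_EPOCH = int(EPOCH_MINUTES * 60 / SAMPLE_PERIOD_S)  # 960
MAX_INTENSITY = 63
DEFAULT_SCALE_DIVISOR = 15  # ceil(960 / 64)

INTENSITY_CSV_COLUMNS = ("child_id", "epoch_start", "intensity")


@dataclass
class RawAccelerationSeries:
    """Raw acceleration magnitudes sampled at a fixed 0.125 s period.

    ``reference_threshold`` is in the same (unspecified) device units as
    the samples; a sample counts toward the activity value when it is
    strictly greater than the threshold.
    """

    start_time: datetime
    samples: np.ndarray
    reference_threshold: float
    sample_period: float = SAMPLE_PERIOD_S

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_period != SAMPLE_PERIOD_S:
            raise ValidationError(
                f"sample_period must be {SAMPLE_PERIOD_S} s, got {self.sample_period}"
            )
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if np.any(self.samples < 0):
            raise ValidationError("acceleration magnitudes must be non-negative")


@dataclass
class ActivityIntensitySeries:
    """Contiguous 2-minute epochs of integer activity intensity in [0, 63]."""

    child_id: str
    start_time: datetime
    intensities: np.ndarray
    epoch_length_min: int = EPOCH_MINUTES

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.epoch_length_min != EPOCH_MINUTES:
            raise ValidationError(f"epoch length must be {EPOCH_MINUTES} min")
        if self.intensities.ndim != 1 or self.intensities.size < 1:
            raise ValidationError("intensities must be a non-empty 1-D sequence")
        if not np.issubdtype(self.intensities.dtype, np.integer):
            as_int = self.intensities.astype(np.int64)
            if np.any(as_int != self.intensities):
                raise ValidationError("intensities must be integers")
            self.intensities = as_int
        if np.any((self.intensities < 0) | (self.intensities > MAX_INTENSITY)):
            raise ValidationError(f"intensities must lie in [0, {MAX_INTENSITY}]")

    def __len__(self) -> int:
        return int(self.intensities.size)

    def epoch_start(self, index: int) -> datetime:
        return self.start_time + timedelta(minutes=EPOCH_MINUTES * index)

    @property
    def end_time(self) -> datetime:
        return self.epoch_start(len(self))

    def epoch_starts(self) -> Iterator[datetime]:
        for i in range(len(self)):
            yield self.epoch_start(i)


def bin_accelerations(
    raw: RawAccelerationSeries, *, allow_truncate: bool = False
) -> np.ndarray:
    """Count threshold crossings per 2-minute window ("activity values").

    Each window covers 960 consecutive samples; the activity value is the
    number of samples strictly exceeding ``raw.reference_threshold``.  A
    trailing partial window is rejected unless ``allow_truncate`` drops it.
    """
    n = raw.samples.size
    n_full, remainder = divmod(n, SAMPLES_PER_EPOCH)
    if remainder and not allow_truncate:
        raise ValidationError(
            f"series length {n} is not a multiple of {SAMPLES_PER_EPOCH} samples "
            f"({remainder} trailing samples); pass allow_truncate=True to drop them"
        )
    if n_full == 0:
        raise ValidationError("series shorter than one 2-minute window")
    trimmed = raw.samples[: n_full * SAMPLES_PER_EPOCH]
    crossings = trimmed > raw.reference_threshold
    return crossings.reshape(n_full, SAMPLES_PER_EPOCH).sum(axis=1).astype(np.int64)


def intensity_from_activity(
    activity_value, scale_divisor: int = DEFAULT_SCALE_DIVISOR
):
    """Compress activity values to the 64-level intensity scale.

    ``floor(value / scale_divisor)`` clipped to [0, 63]; monotone
    non-decreasing, 0 -> 0, saturating at 63.  Accepts scalars or arrays.
    """
    values = np.asarray(activity_value)
    if np.any(values < 0):
        raise ValidationError("activity values must be non-negative")
    if scale_divisor < 1:
        raise ValidationError("scale_divisor must be >= 1")
    out = np.minimum(values // scale_divisor, MAX_INTENSITY).astype(np.int64)
    return int(out) if np.isscalar(activity_value) else out


def raw_to_intensity_series(
    raw: RawAccelerationSeries,
    child_id: str,
    *,
    scale_divisor: int = DEFAULT_SCALE_DIVISOR,
    allow_truncate: bool = False,
) -> ActivityIntensitySeries:
    """Full binning stage: raw samples to an intensity series."""
    activity = bin_accelerations(raw, allow_truncate=allow_truncate)
    return ActivityIntensitySeries(
        child_id=child_id,
        start_time=raw.start_time,
        intensities=intensity_from_activity(activity, scale_divisor),
    )


def write_intensity_csv(
    series: ActivityIntensitySeries | Sequence[ActivityIntensitySeries], path
) -> None:
    """Write one or more series to a strict (child_id, epoch_start, intensity) CSV."""
    if isinstance(series, ActivityIntensitySeries):
        series = [series]
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "child_id": s.child_id,
                    "epoch_start": [t.isoformat() for t in s.epoch_starts()],
                    "intensity": s.intensities,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_intensity_csv(path) -> list[ActivityIntensitySeries]:
    """Read a strict intensity CSV back into per-child contiguous series.

    Rows are grouped by ``child_id`` in order of first appearance.  Epochs
    within a child must be contiguous 2-minute steps; any gap raises
    :class:`GapError` naming the missing spans.
    """
    df = pd.read_csv(path)
    if tuple(df.columns) != INTENSITY_CSV_COLUMNS:
        raise ValidationError(
            f"intensity CSV must have columns {INTENSITY_CSV_COLUMNS}, "
            f"got {tuple(df.columns)}"
        )
    if df.empty:
        raise ValidationError("intensity CSV contains no rows")
    out = []
    for child_id, group in df.groupby("child_id", sort=False):
        starts = pd.to_datetime(group["epoch_start"]).to_list()
        gaps = []
        for prev, cur in zip(starts, starts[1:]):
            if cur - prev != timedelta(minutes=EPOCH_MINUTES):
                gaps.append((prev + timedelta(minutes=EPOCH_MINUTES), cur))
        if gaps:
            spans = "; ".join(f"{a.isoformat()} -> {b.isoformat()}" for a, b in gaps)
            raise GapError(
                f"non-contiguous epochs for child {child_id!r}: missing {spans}", gaps
            )
        out.append(
            ActivityIntensitySeries(
                child_id=str(child_id),
                start_time=starts[0].to_pydatetime(),
                intensities=group["intensity"].to_numpy(),
            )
        )
    return out
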