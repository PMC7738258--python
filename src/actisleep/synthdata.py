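"""Synthetic toddler-sleep cohort generator.

Emulates the study design the package analyses: ~10 children wearing an
actigraph for 8 consecutive nights in each of 2 months while a caregiver
keeps an app sleep diary.  Three layers are generated separately so each
pipeline stage can be tested against known truth:

* ground truth — per-night bedtime, sleep-onset latency, wake-up time and
  brief true awakenings, with between-child and between-night variation;
* activity intensities — wake spans draw high 0-63 intensities, sleep is
  near zero except for short Poisson-placed movement bursts (the motor
  arousals that make actigraphy over-count awakenings in toddlers);
* diary records — truth plus caregiver reporting noise: a small bedtime
  entry delay, a larger wake-time error, over-reported latency, and
  binomial thinning of awakenings (caregivers notice only a fraction of
  >5-min episodes).

Defaults are calibrated so the cohort is shaped like a real toddler
cohort: bedtimes ~21:00 +/- 37 min, wake-ups ~6:30 +/- 25 min, diary
night-time sleep ~550 min, ~9 scored vs ~0.4 reported awakenings per
night.  A single global seed fans out to per-stage, per-child-night
substreams so partial re-renders stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np

from .actigraph import ActivityIntensitySeries, EPOCH_MINUTES, MAX_INTENSITY
from .concordance import MEASURES, ConcordanceResult, compare_sources
from .diary import DiaryRecord, SleepSummary, diary_to_summary
from .errors import NoSleepError, ValidationError
from .scoring import NightWindow, summarize_night_actigraphy
from .timeutil import noon_of

# analysis frame for every simulated night: 18:00 -> 10:00 next day
WINDOW_START_MIN = 6 * 60  # minutes since noon
WINDOW_END_MIN = 22 * 60
N_EPOCHS = (WINDOW_END_MIN - WINDOW_START_MIN) // EPOCH_MINUTES

# substream stage tags
_STAGE_TRUTH_CHILD = 0
_STAGE_TRUTH_NIGHT = 1
_STAGE_ACTIVITY = 2
_STAGE_DIARY_CHILD = 3
_STAGE_DIARY_NIGHT = 4


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and ground-truth parameters.

    Clock means are minutes since noon (540 = 21:00, 1110 = 06:30).
    Between/within SDs split each clock quantity into a stable per-child
    habit and night-to-night variation; their quadrature sums give the
    cohort-level spreads (~37 min for bedtime, ~25 min for wake-up).
    """

    n_children: int = 10
    nights_per_month: int = 8
    months: int = 2
    seed: int = 0
    start_date: date = date(2024, 6, 3)  # a Monday; 8 nights include one weekend
    month_offset_days: int = 28  # keeps weekday structure aligned across months
    bedtime_mean_min: float = 540.0  # 21:00
    bedtime_between_sd: float = 25.0
    bedtime_within_sd: float = 27.0
    waketime_mean_min: float = 1110.0  # 06:30
    waketime_between_sd: float = 15.0
    waketime_within_sd: float = 20.0
    latency_mean: float = 5.0  # true sleep-onset latency, minutes
    latency_between_sd: float = 3.0
    latency_within_sd: float = 4.0
    true_awakening_rate: float = 1.5  # Poisson mean, events per night
    awakening_min_duration: float = 2.0  # minutes; shifted-exponential floor
    awakening_mean_extra: float = 6.0  # exponential mean above the floor
    weekend_wake_shift: float = 15.0  # weekend wake-ups this much later

    def __post_init__(self) -> None:
        for name in (
            "bedtime_between_sd", "bedtime_within_sd", "waketime_between_sd",
            "waketime_within_sd", "latency_between_sd", "latency_within_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.true_awakening_rate < 0:
            raise ValidationError("true_awakening_rate must be >= 0")
        if self.n_children < 1 or self.nights_per_month < 1 or self.months < 1:
            raise ValidationError("cohort dimensions must be >= 1")


@dataclass(frozen=True)
class MovementModel:
    """How sleep/wake states translate into 0-63 activity intensities."""

    wake_intensity_mean: float = 35.0
    wake_intensity_sd: float = 10.0
    wake_intensity_min: int = 5
    sleep_base_intensity: int = 0
    burst_rate_per_hour: float = 1.0  # motor arousals during sleep
    burst_duration_epochs: int = 1
    burst_intensity_mean: float = 20.0
    burst_intensity_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.burst_rate_per_hour < 0:
            raise ValidationError("burst_rate_per_hour must be >= 0")
        if not (0 <= self.sleep_base_intensity <= MAX_INTENSITY):
            raise ValidationError("sleep_base_intensity must lie in [0, 63]")

    @classmethod
    def noiseless(cls) -> "MovementModel":
        """Quiet-wakefulness preset for timing-recovery experiments.

        Wake intensity is a constant 3 so a wake epoch's spillover into
        neighbouring windows stays below the wake threshold beyond one
        epoch, and there are no movement bursts: classification error is
        then pure epoch quantisation.
        """
        return cls(
            wake_intensity_mean=3.0,
            wake_intensity_sd=0.0,
            wake_intensity_min=3,
            sleep_base_intensity=0,
            burst_rate_per_hour=0.0,
        )


@dataclass(frozen=True)
class DiaryNoiseModel:
    """Caregiver reporting noise layered on top of ground truth."""

    bedtime_bias: float = 13.0  # entry logged after the settling routine
    bedtime_child_sd: float = 10.0  # stable per-caregiver reporting offset
    bedtime_error_sd: float = 10.0  # night-to-night entry error
    waketime_bias: float = -8.0  # caregivers log the first morning stirring
    waketime_child_sd: float = 8.0
    waketime_error_sd: float = 35.0  # wake-ups are reported far less precisely
    latency_bias: float = 15.0  # caregivers over-estimate settling time
    latency_error_sd: float = 5.0
    awakening_notice_prob: float = 0.45  # chance a >5-min episode is noticed
    rounding_min: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.awakening_notice_prob <= 1.0):
            raise ValidationError("awakening_notice_prob must lie in [0, 1]")
        for name in ("bedtime_child_sd", "bedtime_error_sd", "waketime_child_sd",
                     "waketime_error_sd", "latency_error_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.rounding_min < 1:
            raise ValidationError("rounding_min must be >= 1")

    @classmethod
    def noiseless(cls) -> "DiaryNoiseModel":
        """Perfect reporter: diary summaries equal ground truth."""
        return cls(
            bedtime_bias=0.0, bedtime_child_sd=0.0, bedtime_error_sd=0.0,
            waketime_bias=0.0, waketime_child_sd=0.0, waketime_error_sd=0.0,
            latency_bias=0.0, latency_error_sd=0.0,
            awakening_notice_prob=1.0, rounding_min=1,
        )


@dataclass(frozen=True)
class NightTruth:
    """Ground truth for one child-night, all clocks as datetimes."""

    child_id: str
    child_index: int
    month: int
    night_index: int
    night_date: date
    bedtime: datetime
    sleep_onset: datetime
    wake_time: datetime
    latency_min: float
    awakenings: tuple[tuple[datetime, datetime], ...]

    @property
    def is_weekend(self) -> bool:
        return self.night_date.weekday() >= 5

    @property
    def sleep_minutes(self) -> float:
        """True sleep: onset-to-wake span minus true awakening time."""
        span = (self.wake_time - self.sleep_onset).total_seconds() / 60.0
        awake = sum((b - a).total_seconds() / 60.0 for a, b in self.awakenings)
        return span - awake


def night_window(truth: NightTruth) -> NightWindow:
    noon = noon_of(truth.night_date)
    return NightWindow(
        night_date=truth.night_date,
        window_start=noon + timedelta(minutes=WINDOW_START_MIN),
        window_end=noon + timedelta(minutes=WINDOW_END_MIN),
    )


def _child_id(i: int) -> str:
    return f"child{i + 1:02d}"


def generate_truth(cfg: CohortConfig, seed: int | None = None) -> list[NightTruth]:
    """Draw ground-truth sleep schedules for the whole cohort."""
    seed = cfg.seed if seed is None else seed
    truths: list[NightTruth] = []
    for i in range(cfg.n_children):
        rc = _rng(seed, _STAGE_TRUTH_CHILD, i)
        bed_habit = rc.normal(0.0, cfg.bedtime_between_sd)
        wake_habit = rc.normal(0.0, cfg.waketime_between_sd)
        child_latency = max(0.0, rc.normal(cfg.latency_mean, cfg.latency_between_sd))
        for month in range(1, cfg.months + 1):
            month_start = cfg.start_date + timedelta(
                days=(month - 1) * cfg.month_offset_days
            )
            for j in range(cfg.nights_per_month):
                night_date = month_start + timedelta(days=j)
                rn = _rng(seed, _STAGE_TRUTH_NIGHT, i, month, j)
                bed = cfg.bedtime_mean_min + bed_habit + rn.normal(0.0, cfg.bedtime_within_sd)
                wake = (
                    cfg.waketime_mean_min + wake_habit
                    + rn.normal(0.0, cfg.waketime_within_sd)
                )
                if night_date.weekday() >= 5:
                    wake += cfg.weekend_wake_shift
                # keep the night inside the 18:00-10:00 analysis window
                bed = float(np.clip(bed, WINDOW_START_MIN + 30, 840.0))
                wake = float(np.clip(wake, 930.0, WINDOW_END_MIN - 30))
                latency = max(0.0, rn.normal(child_latency, cfg.latency_within_sd))
                onset = bed + latency
                if wake - onset < 120.0:
                    raise ValidationError(
                        "infeasible config: night shorter than 2 h of sleep"
                    )
                awakenings = _place_awakenings(cfg, rn, onset, wake)
                noon = noon_of(night_date)
                truths.append(
                    NightTruth(
                        child_id=_child_id(i),
                        child_index=i,
                        month=month,
                        night_index=j,
                        night_date=night_date,
                        bedtime=noon + timedelta(minutes=bed),
                        sleep_onset=noon + timedelta(minutes=onset),
                        wake_time=noon + timedelta(minutes=wake),
                        latency_min=latency,
                        awakenings=tuple(
                            (noon + timedelta(minutes=a), noon + timedelta(minutes=b))
                            for a, b in awakenings
                        ),
                    )
                )
    return truths


def _place_awakenings(
    cfg: CohortConfig, rng: np.random.Generator, onset: float, wake: float
) -> list[tuple[float, float]]:
    """Place Poisson-many non-overlapping awakenings inside the sleep span."""
    n = int(rng.poisson(cfg.true_awakening_rate))
    if n == 0:
        return []
    durations = cfg.awakening_min_duration + rng.exponential(
        cfg.awakening_mean_extra, size=n
    )
    lo, hi = onset + 15.0, wake - 15.0
    if durations.sum() > (hi - lo) * 0.5:
        raise ValidationError(
            "infeasible config: awakenings cannot fit inside the sleep span"
        )
    placed: list[tuple[float, float]] = []
    for d in durations:
        for _ in range(200):
            a = rng.uniform(lo, hi - d)
            b = a + d
            if all(b <= p or a >= q for p, q in placed):
                placed.append((a, b))
                break
        else:  # pragma: no cover - practically unreachable at default rates
            raise ValidationError("could not place awakenings without overlap")
    return sorted(placed)


def _mark_overlap(mask: np.ndarray, a_min: float, b_min: float) -> None:
    """Mark every epoch overlapping the [a, b) minutes-since-noon interval."""
    k0 = int(np.floor((a_min - WINDOW_START_MIN) / EPOCH_MINUTES))
    k1 = int(np.ceil((b_min - WINDOW_START_MIN) / EPOCH_MINUTES))
    mask[max(k0, 0) : min(k1, mask.size)] = True


def render_activity(
    truths: Sequence[NightTruth],
    movement: MovementModel | None = None,
    seed: int | None = None,
) -> list[ActivityIntensitySeries]:
    """Render one 18:00-10:00 intensity series per child-night."""
    movement = movement or MovementModel()
    seed = 0 if seed is None else seed
    out = []
    for t in truths:
        rng = _rng(seed, _STAGE_ACTIVITY, t.child_index, t.month, t.night_index)
        noon = noon_of(t.night_date)

        def mins(moment: datetime) -> float:
            return (moment - noon).total_seconds() / 60.0

        wake_mask = np.zeros(N_EPOCHS, dtype=bool)
        _mark_overlap(wake_mask, WINDOW_START_MIN, mins(t.sleep_onset))
        _mark_overlap(wake_mask, mins(t.wake_time), WINDOW_END_MIN)
        for a, b in t.awakenings:
            _mark_overlap(wake_mask, mins(a), mins(b))

        intensity = np.full(N_EPOCHS, movement.sleep_base_intensity, dtype=np.int64)
        n_wake = int(wake_mask.sum())
        intensity[wake_mask] = np.clip(
            np.rint(
                rng.normal(
                    movement.wake_intensity_mean, movement.wake_intensity_sd, n_wake
                )
            ),
            movement.wake_intensity_min,
            MAX_INTENSITY,
        ).astype(np.int64)

        if movement.burst_rate_per_hour > 0:
            p = movement.burst_rate_per_hour * EPOCH_MINUTES / 60.0
            sleep_idx = np.flatnonzero(~wake_mask)
            starts = sleep_idx[rng.random(sleep_idx.size) < p]
            for s in starts:
                for k in range(s, min(s + movement.burst_duration_epochs, N_EPOCHS)):
                    if wake_mask[k]:
                        break
                    intensity[k] = int(
                        np.clip(
                            np.rint(
                                rng.normal(
                                    movement.burst_intensity_mean,
                                    movement.burst_intensity_sd,
                                )
                            ),
                            5,
                            MAX_INTENSITY,
                        )
                    )
        out.append(
            ActivityIntensitySeries(
                child_id=t.child_id,
                start_time=noon + timedelta(minutes=WINDOW_START_MIN),
                intensities=intensity,
            )
        )
    return out


def _round_to(value: float, granularity: int) -> float:
    return float(np.rint(value / granularity) * granularity)


def render_diary(
    truths: Sequence[NightTruth],
    noise: DiaryNoiseModel | None = None,
    seed: int | None = None,
) -> list[DiaryRecord]:
    """Generate one caregiver diary record per child-night."""
    noise = noise or DiaryNoiseModel()
    seed = 0 if seed is None else seed
    child_bias: dict[int, tuple[float, float]] = {}
    records = []
    for t in truths:
        if t.child_index not in child_bias:
            rc = _rng(seed, _STAGE_DIARY_CHILD, t.child_index)
            child_bias[t.child_index] = (
                rc.normal(0.0, noise.bedtime_child_sd),
                rc.normal(0.0, noise.waketime_child_sd),
            )
        bed_off, wake_off = child_bias[t.child_index]
        rng = _rng(seed, _STAGE_DIARY_NIGHT, t.child_index, t.month, t.night_index)
        noon = noon_of(t.night_date)
        bed_true = (t.bedtime - noon).total_seconds() / 60.0
        wake_true = (t.wake_time - noon).total_seconds() / 60.0

        bed_rep = _round_to(
            bed_true + noise.bedtime_bias + bed_off + rng.normal(0, noise.bedtime_error_sd),
            noise.rounding_min,
        )
        wake_rep = _round_to(
            wake_true + noise.waketime_bias + wake_off + rng.normal(0, noise.waketime_error_sd),
            noise.rounding_min,
        )
        wake_rep = max(wake_rep, bed_rep + 60.0)  # keep the night well-formed
        latency_rep = max(
            0.0,
            _round_to(
                t.latency_min + noise.latency_bias + rng.normal(0, noise.latency_error_sd),
                noise.rounding_min,
            ),
        )
        latency_rep = min(latency_rep, wake_rep - bed_rep)

        noticeable = sum(
            1 for a, b in t.awakenings if (b - a).total_seconds() / 60.0 > 5.0
        )
        reported = int(rng.binomial(noticeable, noise.awakening_notice_prob))

        records.append(
            DiaryRecord(
                child_id=t.child_id,
                night_date=t.night_date,
                bedtime=_minutes_to_time(bed_rep),
                wake_up=_minutes_to_time(wake_rep),
                sleep_latency_min=int(latency_rep),
                reported_awakenings=reported,
                nap_start=time(13, 0),
                nap_end=time(14, int(rng.integers(0, 60))),
                screen_time_min=int(np.clip(rng.normal(60, 25), 0, 240)),
                outdoor_time_min=int(np.clip(rng.normal(90, 35), 0, 300)),
                bath_time=time(19, 30),
                dinner_time=time(18, 30),
                prebed_activity="picture books",
                stress_level=int(rng.integers(1, 6)),
            )
        )
    return records


def _minutes_to_time(minutes_since_noon: float) -> time:
    total = int(round(minutes_since_noon + 12 * 60)) % (24 * 60)
    return time(total // 60, total % 60)


@dataclass
class ExperimentResult:
    """Everything the simulated concordance experiment produced."""

    results: dict[tuple[str, int], ConcordanceResult]
    actigraphy_summaries: list[SleepSummary]
    diary_summaries: list[SleepSummary]
    truths: list[NightTruth]
    n_unscorable_nights: int = 0


def score_cohort(
    truths: Sequence[NightTruth],
    series: Sequence[ActivityIntensitySeries],
    **scoring_kwargs,
) -> tuple[list[SleepSummary], int]:
    """Score every rendered night; returns (summaries, n_unscorable)."""
    summaries, failed = [], 0
    for t, s in zip(truths, series):
        try:
            summaries.append(
                summarize_night_actigraphy(
                    s, night_window(t), month=t.month, **scoring_kwargs
                )
            )
        except NoSleepError:
            failed += 1
    return summaries, failed


def run_concordance_experiment(
    cfg: CohortConfig | None = None,
    movement: MovementModel | None = None,
    noise: DiaryNoiseModel | None = None,
    seed: int | None = None,
    correlation_pooling: str = "nights",
) -> ExperimentResult:
    """Full pipeline: truth -> activity -> scoring and truth -> diary,
    then diary-vs-actigraphy concordance for all four measures x months.
    """
    cfg = cfg or CohortConfig()
    seed = cfg.seed if seed is None else seed
    truths = generate_truth(cfg, seed)
    series = render_activity(truths, movement, seed)
    act_summaries, failed = score_cohort(truths, series)
    diary_records = render_diary(truths, noise, seed)
    month_of = {
        (t.child_id, t.night_date): t.month for t in truths
    }
    diary_summaries = [
        diary_to_summary(r, month=month_of[(r.child_id, r.night_date)])
        for r in diary_records
    ]
    all_summaries = act_summaries + diary_summaries
    results = {}
    for measure in MEASURES:
        for month in range(1, cfg.months + 1):
            results[(measure, month)] = compare_sources(
                all_summaries,
                measure,
                month=month,
                correlation_pooling=correlation_pooling,
            )
    return ExperimentResult(
        results=results,
        actigraphy_summaries=act_summaries,
        diary_summaries=diary_summaries,
        truths=truths,
        n_unscorable_nights=failed,
    )
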