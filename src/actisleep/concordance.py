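"""Diary vs actigraphy method-agreement statistics.

The comparison design follows small-cohort agreement practice: nights
are first averaged within each participant (clock times on the
minutes-since-noon axis, so cross-midnight bedtimes average correctly),
then the two sources are compared across participants with a two-tailed
paired t test (df = n_participants - 1).  Pearson correlations between
the sources are, by default, computed across pooled child-nights —
participant-level n of ~10 cannot resolve the correlations of interest —
with participant-level means available as an option.

The t and r formulas are implemented directly (mean difference over its
standard error; product-moment correlation with a t-transform p value)
so they can be cross-checked against independent library routines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .diary import SleepSummary
from .errors import EmptyAggregateError, InsufficientPairsError, ValidationError

MEASURES = ("bedtime", "wake_up", "nighttime_sleep", "awakenings")
CLOCK_MEASURES = ("bedtime", "wake_up")
STRATA = ("all", "weekday", "weekend")


def summary_value(summary: SleepSummary, measure: str) -> float:
    """Extract one measure from a summary on its analysis axis.

    Clock measures come back as minutes since noon of the night's date;
    durations in minutes; awakenings as counts.
    """
    if measure == "bedtime":
        return summary.bedtime_minutes()
    if measure == "wake_up":
        return summary.wake_up_minutes()
    if measure == "nighttime_sleep":
        return float(summary.nighttime_sleep)
    if measure == "awakenings":
        return float(summary.awakenings)
    raise ValidationError(f"unknown measure {measure!r}; choose from {MEASURES}")


def _stratum_filter(stratum: str) -> Callable[[SleepSummary], bool]:
    if stratum == "all":
        return lambda s: True
    if stratum == "weekday":
        return lambda s: not s.is_weekend
    if stratum == "weekend":
        return lambda s: s.is_weekend
    raise ValidationError(f"unknown stratum {stratum!r}; choose from {STRATA}")


@dataclass(frozen=True)
class ParticipantAggregate:
    """Per-participant mean/SD of one measure over the retained nights."""

    child_id: str
    measure: str
    source: str
    mean: float
    sd: float  # sample (n-1) SD; NaN when only one night
    n_nights: int
    month: int | None = None


@dataclass(frozen=True)
class ConcordanceResult:
    """Paired-difference statistics for one measure, diary vs actigraphy."""

    measure: str
    month: int | None
    stratum: str
    n: int  # participants contributing both sources
    n_dropped: int  # participants missing one source
    mean_actigraphy: float
    mean_diary: float
    t_statistic: float
    df: int
    p_value: float
    pearson_r: float
    r_squared: float
    correlation_pooling: str


def aggregate_participant(
    summaries: Sequence[SleepSummary],
    measure: str,
    stratum: str = "all",
    month: int | None = None,
) -> ParticipantAggregate:
    """Mean and sample SD of one measure over one child's nights.

    All summaries must share one child and one source.  A single
    surviving night yields a defined mean but an undefined (NaN) sample
    SD; zero surviving nights is an error.
    """
    keep = [s for s in summaries if _stratum_filter(stratum)(s)]
    if month is not None:
        keep = [s for s in keep if s.month == month]
    if not keep:
        raise EmptyAggregateError(
            f"no nights left for measure {measure!r} after stratum={stratum!r}, "
            f"month={month!r}"
        )
    children = {s.child_id for s in keep}
    sources = {s.source for s in keep}
    if len(children) != 1 or len(sources) != 1:
        raise ValidationError(
            "aggregate_participant expects one child and one source; got "
            f"children={sorted(children)}, sources={sorted(sources)}"
        )
    values = np.array([summary_value(s, measure) for s in keep], dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return ParticipantAggregate(
        child_id=keep[0].child_id,
        measure=measure,
        source=keep[0].source,
        mean=float(values.mean()),
        sd=sd,
        n_nights=int(values.size),
        month=month,
    )


def paired_t_two_tailed(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Two-tailed paired-samples t test: t = mean(d) / (sd(d)/sqrt(n)).

    Differences d = a - b; df = n - 1; p from the t distribution.  When
    the differences have zero variance the statistic degenerates: t = 0,
    p = 1 for identical pairs, otherwise t = +/-inf with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise InsufficientPairsError("paired t test needs at least 2 pairs")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, md), df, 0.0
    t = md / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def pearson_correlation(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Product-moment correlation with a two-tailed t-transform p value.

    Returns (r, r_squared, p).  Requires n >= 3 and non-zero variance in
    both inputs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("correlation inputs must be equal-length 1-D sequences")
    n = a.size
    if n < 3:
        raise InsufficientPairsError("correlation needs at least 3 pairs")
    da, db = a - a.mean(), b - b.mean()
    denom = math.sqrt(float(da @ da) * float(db @ db))
    if denom == 0.0:
        raise ValidationError("correlation undefined: an input has zero variance")
    r = float(da @ db) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, r * r, float(p)


def _split_sources(
    summaries: Iterable[SleepSummary],
    stratum: str,
    month: int | None,
) -> dict[str, dict[str, list[SleepSummary]]]:
    """child_id -> source -> summaries surviving the filters."""
    keep = _stratum_filter(stratum)
    out: dict[str, dict[str, list[SleepSummary]]] = {}
    for s in summaries:
        if not keep(s):
            continue
        if month is not None and s.month != month:
            continue
        out.setdefault(s.child_id, {}).setdefault(s.source, []).append(s)
    return out


def compare_sources(
    summaries: Iterable[SleepSummary],
    measure: str,
    month: int | None = None,
    stratum: str = "all",
    correlation_pooling: str = "nights",
) -> ConcordanceResult:
    """Full agreement analysis of one measure for one month/stratum.

    Children contributing only one source are dropped (with their count
    reported), mirroring attrition in real cohorts.  The paired t test
    runs across participants on per-participant means; the correlation
    is computed over pooled child-nights matched by night date
    (``correlation_pooling="nights"``, default) or over the participant
    means (``"participants"``).
    """
    if correlation_pooling not in ("nights", "participants"):
        raise ValidationError(
            f"correlation_pooling must be 'nights' or 'participants', "
            f"got {correlation_pooling!r}"
        )
    by_child = _split_sources(summaries, stratum, month)
    paired_children = sorted(
        c for c, by_src in by_child.items()
        if "actigraphy" in by_src and "diary" in by_src
    )
    n_dropped = len(by_child) - len(paired_children)
    if len(paired_children) < 2:
        raise InsufficientPairsError(
            f"need >= 2 children with both sources, have {len(paired_children)}"
        )
    act_means, diary_means = [], []
    for child in paired_children:
        act_means.append(
            aggregate_participant(by_child[child]["actigraphy"], measure).mean
        )
        diary_means.append(
            aggregate_participant(by_child[child]["diary"], measure).mean
        )
    t, df, p = paired_t_two_tailed(act_means, diary_means)

    if correlation_pooling == "participants":
        xs, ys = act_means, diary_means
    else:
        xs, ys = [], []
        for child in paired_children:
            act_by_night = {s.night_date: s for s in by_child[child]["actigraphy"]}
            for s in by_child[child]["diary"]:
                match = act_by_night.get(s.night_date)
                if match is not None:
                    xs.append(summary_value(match, measure))
                    ys.append(summary_value(s, measure))
    try:
        r, r2, _ = pearson_correlation(xs, ys)
    except ValidationError:
        # a degenerate (constant) measure has no defined correlation
        r, r2 = float("nan"), float("nan")
    return ConcordanceResult(
        measure=measure,
        month=month,
        stratum=stratum,
        n=len(paired_children),
        n_dropped=n_dropped,
        mean_actigraphy=float(np.mean(act_means)),
        mean_diary=float(np.mean(diary_means)),
        t_statistic=t,
        df=df,
        p_value=p,
        pearson_r=r,
        r_squared=r2,
        correlation_pooling=correlation_pooling,
    )


def month_contrast(
    summaries: Iterable[SleepSummary],
    measure: str,
    stratum: str = "all",
    source: str = "actigraphy",
) -> tuple[float, int, float]:
    """Paired t test of month 1 vs month 2 per-participant means.

    Children present in both months for the chosen source are paired;
    returns (t, df, p) with the difference taken month1 - month2.
    """
    per_month: dict[int, dict[str, float]] = {1: {}, 2: {}}
    for m in (1, 2):
        by_child = _split_sources(summaries, stratum, m)
        for child, by_src in by_child.items():
            if source in by_src:
                per_month[m][child] = aggregate_participant(by_src[source], measure).mean
    common = sorted(set(per_month[1]) & set(per_month[2]))
    if len(common) < 2:
        raise InsufficientPairsError(
            f"need >= 2 children present in both months, have {len(common)}"
        )
    a = [per_month[1][c] for c in common]
    b = [per_month[2][c] for c in common]
    return paired_t_two_tailed(a, b)
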