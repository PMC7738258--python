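"""Participant aggregation and the paired-t / Pearson agreement statistics."""

import math
from datetime import date, datetime, timedelta

import numpy as np
import pytest
from scipy import stats

from actisleep import (
    EmptyAggregateError,
    InsufficientPairsError,
    SleepSummary,
    ValidationError,
    aggregate_participant,
    compare_sources,
    month_contrast,
    paired_t_two_tailed,
    pearson_correlation,
)


def summary(child="c1", night=date(2024, 6, 3), source="diary", bed="21:00",
            wake="06:30", sleep=550.0, awak=1.0, month=1):
    bh, bm = map(int, bed.split(":"))
    wh, wm = map(int, wake.split(":"))
    bed_dt = datetime(night.year, night.month, night.day, bh, bm)
    if bh < 12:
        bed_dt += timedelta(days=1)
    wake_dt = datetime(night.year, night.month, night.day, wh, wm)
    if wh < 12:
        wake_dt += timedelta(days=1)
    span = (wake_dt - bed_dt).total_seconds() / 60.0
    return SleepSummary(
        child_id=child, night_date=night, source=source, bedtime=bed_dt,
        wake_up=wake_dt, nighttime_sleep=min(sleep, span), awakenings=awak,
        is_weekend=night.weekday() >= 5, month=month,
    )


class TestAggregateParticipant:
    def test_mean_and_sample_sd(self):
        nights = [summary(sleep=540), summary(night=date(2024, 6, 4), sleep=560)]
        agg = aggregate_participant(nights, "nighttime_sleep")
        assert agg.mean == 550
        assert agg.sd == pytest.approx(14.142135, abs=1e-5)
        assert agg.n_nights == 2

    def test_single_night_has_undefined_sample_sd(self):
        agg = aggregate_participant([summary()], "nighttime_sleep")
        assert agg.n_nights == 1 and math.isnan(agg.sd)

    def test_cross_midnight_bedtimes_average_on_unrolled_axis(self):
        nights = [
            summary(bed="23:50"),
            summary(night=date(2024, 6, 4), bed="00:10"),
        ]
        agg = aggregate_participant(nights, "bedtime")
        assert agg.mean == 720  # midnight on the minutes-since-noon axis

    def test_weekend_stratum_filters_nights(self):
        nights = [
            summary(night=date(2024, 6, 7), sleep=500),  # Friday
            summary(night=date(2024, 6, 8), sleep=560),  # Saturday
        ]
        assert aggregate_participant(nights, "nighttime_sleep", "weekend").mean == 560
        assert aggregate_participant(nights, "nighttime_sleep", "weekday").mean == 500

    def test_empty_after_filter_is_an_error(self):
        with pytest.raises(EmptyAggregateError):
            aggregate_participant([summary(night=date(2024, 6, 3))], "bedtime", "weekend")

    def test_mixed_children_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_participant([summary(child="a"), summary(child="b")], "bedtime")


class TestPairedT:
    def test_identical_samples(self):
        t, df, p = paired_t_two_tailed([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_hand_computed_example(self):
        # d = (1, 2, 3): mean 2, sd 1, t = 2 / (1/sqrt(3))
        t, df, p = paired_t_two_tailed([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-6)
        assert t == pytest.approx(3.4641016, abs=1e-6)
        assert df == 2

    def test_zero_variance_nonzero_difference(self):
        t, df, p = paired_t_two_tailed([2.0, 3.0], [1.0, 2.0])
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a, b = rng.normal(0, 5, n), rng.normal(1, 5, n)
            t, df, p = paired_t_two_tailed(a, b)
            ref = stats.ttest_rel(a, b)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            assert df == n - 1

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientPairsError):
            paired_t_two_tailed([1.0], [2.0])


class TestPearson:
    def test_perfect_linear_relations(self):
        a = np.arange(10.0)
        r, r2, p = pearson_correlation(a, 2 * a + 1)
        assert (r, r2) == (1.0, 1.0)
        r, _, _ = pearson_correlation(a, -a)
        assert r == -1.0

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 50))
            a = rng.normal(0, 3, n)
            b = 0.5 * a + rng.normal(0, 2, n)
            r, r2, p = pearson_correlation(a, b)
            ref = stats.pearsonr(a, b)
            assert r == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            assert r2 == pytest.approx(r * r, abs=1e-15)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def cohort(n_children=4, nights=4, act_shift=0.0):
    """Paired diary/actigraphy summaries; actigraphy sleep shifted by act_shift."""
    out = []
    rng = np.random.default_rng(7)
    for i in range(n_children):
        for j in range(nights):
            night = date(2024, 6, 3) + timedelta(days=j)
            sleep = 520 + 10 * i + 5 * j
            out.append(summary(child=f"c{i}", night=night, source="diary", sleep=sleep))
            out.append(
                summary(
                    child=f"c{i}", night=night, source="actigraphy",
                    sleep=sleep + act_shift + rng.normal(0, 1),
                )
            )
    return out


class TestCompareSources:
    def test_identical_sources_give_zero_t(self):
        summaries = cohort(act_shift=0)
        # strip the tiny noise: rebuild actigraphy equal to diary
        summaries = [s for s in summaries if s.source == "diary"]
        mirrored = [
            SleepSummary(**{**s.__dict__, "source": "actigraphy"}) for s in summaries
        ]
        res = compare_sources(summaries + mirrored, "nighttime_sleep", month=1)
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_shift_direction_and_df(self):
        res = compare_sources(cohort(act_shift=-80), "nighttime_sleep", month=1)
        assert res.t_statistic < 0
        assert res.mean_actigraphy < res.mean_diary
        assert res.df == res.n - 1 == 3

    def test_child_missing_one_source_is_dropped(self):
        summaries = cohort(act_shift=-80)
        summaries = [
            s for s in summaries if not (s.child_id == "c0" and s.source == "actigraphy")
        ]
        res = compare_sources(summaries, "nighttime_sleep", month=1)
        assert res.n == 3 and res.n_dropped == 1 and res.df == 2

    def test_permutation_invariant_to_child_order(self, rng):
        summaries = cohort(act_shift=-30)
        shuffled = list(summaries)
        rng.shuffle(shuffled)
        a = compare_sources(summaries, "nighttime_sleep", month=1)
        b = compare_sources(shuffled, "nighttime_sleep", month=1)
        assert a.t_statistic == pytest.approx(b.t_statistic, rel=1e-9)
        assert a.pearson_r == pytest.approx(b.pearson_r, abs=1e-9)

    def test_participant_level_correlation_option(self):
        res = compare_sources(
            cohort(act_shift=-30), "nighttime_sleep", month=1,
            correlation_pooling="participants",
        )
        assert res.correlation_pooling == "participants"
        assert -1 <= res.pearson_r <= 1


class TestMonthContrast:
    def _two_month_cohort(self, shift_min=0.0):
        out = []
        for i in range(5):
            for month, base in ((1, 500.0), (2, 500.0 + shift_min)):
                for j in range(3):
                    night = date(2024, 6 if month == 1 else 7, 3 + j)
                    out.append(
                        summary(
                            child=f"c{i}", night=night, source="actigraphy",
                            sleep=base + 7 * i + 3 * j, month=month,
                        )
                    )
        return out

    def test_identical_months_give_zero_t(self):
        t, df, p = month_contrast(self._two_month_cohort(0.0), "nighttime_sleep")
        assert t == 0.0 and p == 1.0 and df == 4

    def test_month_two_increase_gives_negative_t(self):
        t, _, p = month_contrast(self._two_month_cohort(25.0), "nighttime_sleep")
        assert t < 0 and p < 0.01  # month1 - month2 < 0
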