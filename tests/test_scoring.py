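"""The five-coefficient sleep/wake classifier and night-level measures."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actisleep import (
    ClassifierWeights,
    NightWindow,
    NoSleepError,
    SleepWakeSeries,
    ValidationError,
    classify_series,
    detect_onset_offset,
    extract_wake_events,
    nighttime_sleep_actigraphy,
    score_epoch,
    summarize_night_actigraphy,
)
from actisleep.scoring import SLEEP, UNDEFINED, WAKE

START = datetime(2024, 6, 3, 18, 0)
COEFFS = (0.24669, 0.2562, 0.408771, 0.155046, 0.136728)


def oracle_z(window):
    """Independent epoch-wise application of the printed formula."""
    return sum(c * x for c, x in zip(COEFFS, window))


def make_sw(labels, child_id="c", start=START):
    labels = np.asarray(labels, dtype=np.int8)
    z = np.where(labels == WAKE, 2.0, 0.0).astype(float)
    z[labels == UNDEFINED] = np.nan
    return SleepWakeSeries(child_id=child_id, start_time=start, z_scores=z, labels=labels)


class TestScoreEpoch:
    @pytest.mark.parametrize(
        "window, z_expected, label",
        [
            ((0, 0, 0, 0, 0), 0.0, "sleep"),
            ((1, 1, 1, 1, 1), 1.203435, "wake"),
            ((0, 0, 3, 0, 0), 1.226313, "wake"),
            ((0, 0, 2, 0, 0), 0.817542, "sleep"),
        ],
    )
    def test_hand_derived_points(self, window, z_expected, label):
        z, got = score_epoch(*window)
        assert z == pytest.approx(z_expected, abs=1e-9)
        assert got == label

    def test_wake_exactly_at_threshold(self):
        # coefficients of 0.25 make z exactly representable: 4 x 0.25 = 1.0
        w = ClassifierWeights(0.25, 0.25, 0.25, 0.25, 0.25, wake_threshold=1.0)
        z, label = score_epoch(1, 1, 1, 1, 0, w)
        assert z == 1.0
        assert label == "wake"  # z >= threshold is wake, boundary included

    def test_out_of_range_intensity_rejected(self):
        with pytest.raises(ValidationError):
            score_epoch(0, 0, 64, 0, 0)

    @given(st.lists(st.integers(0, 63), min_size=5, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_every_input(self, window):
        z, _ = score_epoch(*window)
        for i in range(5):
            if window[i] < 63:
                bumped = list(window)
                bumped[i] += 1
                assert score_epoch(*bumped)[0] > z


class TestClassifySeries:
    def test_constant_zero_is_all_sleep_interior(self, make_series):
        sw = classify_series(make_series(np.zeros(10, dtype=int)))
        assert (sw.labels[2:-2] == SLEEP).all()
        assert (sw.labels[[0, 1, -2, -1]] == UNDEFINED).all()
        assert np.isnan(sw.z_scores[[0, 1, -2, -1]]).all()

    def test_constant_63_is_all_wake_with_known_z(self, make_series):
        sw = classify_series(make_series(np.full(10, 63)))
        assert (sw.labels[2:-2] == WAKE).all()
        np.testing.assert_allclose(sw.z_scores[2:-2], 63 * 1.203435, atol=1e-9)

    def test_pad_mode_defines_every_epoch(self, make_series):
        sw = classify_series(make_series([5, 0, 0, 0, 0, 0, 9]), boundary_mode="pad")
        assert not np.isnan(sw.z_scores).any()
        assert (sw.labels != UNDEFINED).all()
        # first epoch under edge padding: x=[5,5,5,0,0]
        assert sw.z_scores[0] == pytest.approx(oracle_z((5, 5, 5, 0, 0)), abs=1e-9)

    def test_short_series_is_all_undefined(self, make_series):
        sw = classify_series(make_series([1, 2, 3, 4]))
        assert (sw.labels == UNDEFINED).all()

    def test_matches_epoch_wise_oracle(self, make_series, rng):
        for _ in range(25):
            x = rng.integers(0, 64, rng.integers(5, 80))
            sw = classify_series(make_series(x))
            for i in range(2, len(x) - 2):
                z = oracle_z(x[i - 2 : i + 3])
                assert sw.z_scores[i] == pytest.approx(z, abs=1e-9)
                assert sw.labels[i] == (WAKE if z >= 1 else SLEEP)


class TestWakeEvents:
    @pytest.mark.parametrize(
        "labels, n_events",
        [
            ([SLEEP, WAKE, WAKE, SLEEP], 0),  # 4 min < 6 min
            ([SLEEP, WAKE, WAKE, WAKE, SLEEP], 1),  # exactly 6 min counts
            ([WAKE] * 3 + [SLEEP] + [WAKE] * 2, 1),  # trailing 4-min run ignored
        ],
    )
    def test_six_minute_rule(self, labels, n_events):
        assert len(extract_wake_events(make_sw(labels))) == n_events

    def test_matches_brute_force_run_scan(self, rng):
        for _ in range(50):
            labels = rng.integers(0, 2, rng.integers(1, 120))
            events = extract_wake_events(make_sw(labels))
            # brute force: count maximal wake runs of length >= 3
            runs, count = 0, 0
            for i, v in enumerate(labels):
                runs = runs + 1 if v == WAKE else 0
                end = i == len(labels) - 1 or labels[i + 1] == SLEEP
                if v == WAKE and end and runs >= 3:
                    count += 1
            assert len(events) == count
            assert all(e.duration_min >= 6 and e.n_epochs >= 3 for e in events)

    def test_undefined_labels_require_policy(self):
        sw = make_sw([UNDEFINED, WAKE, WAKE, WAKE, SLEEP])
        with pytest.raises(ValidationError):
            extract_wake_events(sw)
        assert len(extract_wake_events(sw, undefined_policy="wake")) == 1
        assert len(extract_wake_events(sw, undefined_policy="sleep")) == 1


class TestOnsetOffset:
    def _window(self, sw, hours=4):
        return NightWindow(
            night_date=sw.start_time.date(),
            window_start=sw.start_time,
            window_end=sw.start_time + timedelta(minutes=2 * len(sw)),
        )

    def test_onset_at_first_sustained_run(self):
        sw = make_sw([WAKE, WAKE] + [SLEEP] * 6 + [WAKE] * 3)
        period = detect_onset_offset(sw, self._window(sw), sustained_epochs=3)
        assert period.onset_epoch == 2
        assert period.sleep_onset == START + timedelta(minutes=4)
        assert period.final_wake_epoch == 8

    def test_all_wake_raises_no_sleep(self):
        sw = make_sw([WAKE] * 12)
        with pytest.raises(NoSleepError):
            detect_onset_offset(sw, self._window(sw))

    def test_short_runs_do_not_qualify(self):
        sw = make_sw([SLEEP, SLEEP, WAKE] * 4)
        with pytest.raises(NoSleepError):
            detect_onset_offset(sw, self._window(sw), sustained_epochs=3)

    def test_sleep_to_window_end_has_no_final_wake(self):
        sw = make_sw([WAKE, WAKE] + [SLEEP] * 8)
        with pytest.raises(NoSleepError, match="final waking"):
            detect_onset_offset(sw, self._window(sw), sustained_epochs=3)


class TestNighttimeSleep:
    def test_pure_sleep_span(self):
        labels = [WAKE] + [SLEEP] * 100 + [WAKE] * 3
        sw = make_sw(labels)
        night = NightWindow(
            night_date=START.date(), window_start=START,
            window_end=START + timedelta(minutes=2 * len(labels)),
        )
        period = detect_onset_offset(sw, night, sustained_epochs=3)
        assert nighttime_sleep_actigraphy(sw, period) == 200

    def test_intra_night_wake_excluded(self, rng):
        # conservation: sleep minutes + wake minutes = elapsed onset-offset span
        for _ in range(20):
            labels = (
                [WAKE] * 2 + [SLEEP] * 5
                + list(rng.integers(0, 2, 60))
                + [SLEEP] * 5 + [WAKE] * 4
            )
            sw = make_sw(labels)
            night = NightWindow(
                night_date=START.date(), window_start=START,
                window_end=START + timedelta(minutes=2 * len(labels)),
            )
            period = detect_onset_offset(sw, night, sustained_epochs=5)
            sleep_min = nighttime_sleep_actigraphy(sw, period)
            span = period.final_wake_epoch - period.onset_epoch
            wake_epochs = int(
                (sw.labels[period.onset_epoch : period.final_wake_epoch] == WAKE).sum()
            )
            assert sleep_min == 2 * (span - wake_epochs)
            brute = 2 * sum(
                1 for v in labels[period.onset_epoch : period.final_wake_epoch]
                if v == SLEEP
            )
            assert sleep_min == brute


class TestSummarizeNight:
    def test_composition_matches_individual_operations(self, make_series, rng):
        x = np.concatenate([
            rng.integers(20, 64, 30),  # evening wakefulness
            np.zeros(150, dtype=int),  # sleep
            rng.integers(20, 64, 8),   # a long awakening
            np.zeros(100, dtype=int),  # sleep again
            rng.integers(20, 64, 30),  # morning
        ])
        series = make_series(x)
        night = NightWindow(
            night_date=series.start_time.date(),
            window_start=series.start_time,
            window_end=series.start_time + timedelta(minutes=2 * len(x)),
        )
        summary = summarize_night_actigraphy(series, night)
        sw = classify_series(series)
        period = detect_onset_offset(sw, night)
        events = extract_wake_events(
            sw, start_epoch=period.onset_epoch, end_epoch=period.final_wake_epoch
        )
        assert summary.source == "actigraphy"
        assert summary.bedtime == period.sleep_onset
        assert summary.wake_up == period.final_wake
        assert summary.nighttime_sleep == nighttime_sleep_actigraphy(sw, period)
        assert summary.awakenings == len(events) >= 1

    def test_no_sleep_night_gives_no_partial_summary(self, make_series):
        series = make_series(np.full(60, 63))
        night = NightWindow(
            night_date=series.start_time.date(),
            window_start=series.start_time,
            window_end=series.start_time + timedelta(minutes=120),
        )
        with pytest.raises(NoSleepError):
            summarize_night_actigraphy(series, night)
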