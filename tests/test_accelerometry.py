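"""Nonwear detection, cut-point classification, daily validity and
participant-level aggregation."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actimediate.accelerometry import (
    CutPoints,
    DaySummary,
    EpochSeries,
    aggregate_participant,
    classify_epochs,
    detect_nonwear,
    epochs_to_frame,
    frame_to_series,
    freedson_mvpa_cutpoint,
    summarize_day,
)

from helpers import brute_force_nonwear, series_of as _series

MONDAY = dt.date(2024, 3, 4)
SATURDAY = dt.date(2024, 3, 9)
CP = CutPoints(sedentary_max=25, mvpa_min=574, nonwear_run_min=60)


class TestDetectNonwear:
    def test_sixty_minute_zero_run_is_nonwear(self):
        counts = np.ones(1000, dtype=int)
        counts[100:340] = 0  # 240 epochs x 15 s = 60 min
        wear = detect_nonwear(_series(counts), CP)
        assert not wear[100:340].any()
        assert wear[:100].all() and wear[340:].all()

    def test_run_just_below_threshold_stays_wear(self):
        counts = np.ones(1000, dtype=int)
        counts[100:339] = 0  # 239 epochs = 59.75 min
        assert detect_nonwear(_series(counts), CP).all()

    def test_epoch_len_must_divide_minute(self):
        with pytest.raises(ValueError, match="divide 60"):
            detect_nonwear(_series(np.ones(100), epoch_len=25), CP)

    @settings(max_examples=300, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), p_zero=st.floats(0.3, 0.95))
    def test_matches_brute_force_scanner(self, seed, p_zero):
        rng = np.random.default_rng(seed)
        counts = (rng.random(600) >= p_zero).astype(int)
        wear = detect_nonwear(_series(counts), CP)
        assert np.array_equal(wear, brute_force_nonwear(counts, 240))


class TestClassifyEpochs:
    def test_sedentary_boundary_at_25_counts(self):
        series = _series([25, 26, 573, 574, 9000])
        labels = classify_epochs(series, np.ones(5, bool), CP)
        assert list(labels) == ["sedentary", "lpa", "lpa", "mvpa", "mvpa"]

    def test_wear_zeros_are_sedentary_nonwear_keeps_label(self):
        counts = np.concatenate([np.zeros(10), np.ones(10) * 600, np.zeros(300)])
        series = _series(counts)
        wear = detect_nonwear(series, CP)
        labels = classify_epochs(series, wear, CP)
        assert (labels[:10] == "sedentary").all()  # short zero run during wear
        assert (labels[20:] == "nonwear").all()

    def test_misaligned_mask_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            classify_epochs(_series([1, 2, 3]), np.ones(2, bool), CP)

    def test_sedentary_minutes_monotone_in_cutpoint(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 800, size=2880)
        series = _series(counts)
        wear = detect_nonwear(series, CP)
        prev = -1.0
        for sed_max in range(10, 51):
            cp = CutPoints(sedentary_max=sed_max, mvpa_min=574)
            labels = classify_epochs(series, wear, cp)
            sed = summarize_day(series, labels).sedentary_min
            assert sed >= prev
            prev = sed

    def test_age_specific_threshold_used_when_unpinned(self):
        thr14 = freedson_mvpa_cutpoint(14.0, epoch_len=15)
        series = _series([int(thr14) + 1])
        labels = classify_epochs(series, np.ones(1, bool), CutPoints(), age_years=14.0)
        assert labels[0] == "mvpa"
        with pytest.raises(ValueError, match="age"):
            classify_epochs(series, np.ones(1, bool), CutPoints(), age_years=None)


class TestSummarizeDay:
    def _summary(self, wear_epochs, date):
        counts = np.concatenate(
            [np.ones(wear_epochs, dtype=int) * 10, np.zeros(5760 - wear_epochs, dtype=int)]
        )
        series = _series(counts, date=date)
        wear = detect_nonwear(series, CP)
        return summarize_day(series, classify_epochs(series, wear, CP))

    def test_weekday_validity_boundary_eight_hours(self):
        assert self._summary(480 * 4, MONDAY).valid
        assert not self._summary(480 * 4 - 1, MONDAY).valid  # 479.75 min

    def test_weekend_validity_boundary_seven_hours(self):
        sat = self._summary(420 * 4, SATURDAY)
        assert sat.is_weekend and sat.valid
        assert not self._summary(420 * 4 - 1, SATURDAY).valid

    def test_class_minutes_conserve_wear_on_random_days(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            counts = rng.integers(0, 700, size=2880) * rng.integers(0, 2, size=2880)
            series = _series(counts)
            wear = detect_nonwear(series, CP)
            day = summarize_day(series, classify_epochs(series, wear, CP))
            assert day.sedentary_min + day.lpa_min + day.mvpa_min == pytest.approx(day.wear_min)
            assert day.wear_min + day.nonwear_min == pytest.approx(len(counts) / 4)


def _day(pid, date, sed, valid=True):
    return DaySummary(pid, date, False, sed + 100.0, sed, 80.0, 20.0, 500.0, valid)


class TestAggregateParticipant:
    def test_two_valid_days_excluded(self):
        days = [_day("P1", MONDAY, 500), _day("P1", SATURDAY, 500)]
        agg = aggregate_participant(days, "T0")
        assert agg.n_valid_days == 2 and not agg.included

    def test_mean_of_identical_days(self):
        days = [_day("P1", MONDAY + dt.timedelta(d), 500) for d in range(3)]
        agg = aggregate_participant(days, "T0")
        assert agg.included and agg.avg_sedentary_min == 500

    def test_arithmetic_mean_over_valid_days_only(self):
        sed = [400, 450, 500, 550, 600]
        days = [_day("P1", MONDAY + dt.timedelta(d), s) for d, s in enumerate(sed)]
        days.append(_day("P1", MONDAY + dt.timedelta(6), 9999, valid=False))
        agg = aggregate_participant(days, "T0")
        assert agg.avg_sedentary_min == 500

    def test_empty_and_mixed_participants_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_participant([], "T0")
        with pytest.raises(ValueError, match="multiple participants"):
            aggregate_participant([_day("P1", MONDAY, 500), _day("P2", MONDAY, 500)], "T0")


def test_epoch_csv_roundtrip_reproduces_summaries(tmp_path):
    """Re-running the processing on its own written CSV output is idempotent."""
    rng = np.random.default_rng(5)
    series = [
        EpochSeries("P1", MONDAY + dt.timedelta(d), rng.integers(0, 600, 2880), 15)
        for d in range(3)
    ]
    frame = epochs_to_frame(series)
    path = tmp_path / "epochs.csv"
    frame.to_csv(path, index=False)
    import pandas as pd

    recovered = frame_to_series(pd.read_csv(path), epoch_len=15)
    assert len(recovered) == len(series)
    for a, b in zip(series, sorted(recovered, key=lambda s: s.date)):
        wear_a = detect_nonwear(a, CP)
        wear_b = detect_nonwear(b, CP)
        day_a = summarize_day(a, classify_epochs(a, wear_a, CP))
        day_b = summarize_day(b, classify_epochs(b, wear_b, CP))
        assert vars(day_a) == vars(day_b)


def test_freedson_threshold_scale_and_age_trend():
    # ~2500 counts/min at age 14 -> ~630 counts per 15-s epoch
    thr = freedson_mvpa_cutpoint(14.0, epoch_len=15)
    assert 550 < thr < 700
    assert freedson_mvpa_cutpoint(13.0) < freedson_mvpa_cutpoint(15.0)
    with pytest.raises(ValueError, match="supported range"):
        freedson_mvpa_cutpoint(45.0)
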