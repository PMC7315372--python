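"""Wear, sleep, intensity and inclusion rules against constructed inputs and
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mvpatiming.preprocess import (
    AlgorithmParams,
    Cutpoints,
    DaySummary,
    EpochSeries,
    apply_inclusion_rules,
    classify_intensity,
    detect_nonwear,
    minute_counts,
    score_sleep,
    summarize_day,
)


# ---------------------------------------------------------------------------
# nonwear


def nonwear_oracle(minutes, params):
    """Mark every minute covered by some qualifying length-W window."""
    n = len(minutes)
    w = params.nonwear_window_min
    mask = np.zeros(n, dtype=bool)
    for i in range(n - w + 1):
        win = np.asarray(minutes[i : i + w])
        nz = win > 0
        if nz.sum() <= params.nonwear_spike_max and (
            win[nz] < params.nonwear_spike_ceiling
        ).all():
            mask[i : i + w] = True
    return mask


class TestDetectNonwear:
    def test_ninety_zero_minutes_flagged(self, params):
        counts = np.concatenate([[500] * 10, [0] * 90, [500] * 10])
        mask = detect_nonwear(counts, params)
        assert mask[10:100].all()
        assert not mask[:10].any() and not mask[100:].any()

    def test_interrupt_tolerance_keeps_run_nonwear(self, params):
        counts = np.concatenate([[500] * 5, [0] * 30, [50], [0] * 30, [500] * 5])
        mask = detect_nonwear(counts, params)
        assert mask[5:66].all(), "zero run with one sub-ceiling interrupt stays nonwear"

    def test_spike_above_ceiling_breaks_run(self, params):
        counts = np.concatenate([[0] * 30, [5000], [0] * 30])
        assert not detect_nonwear(counts, params).any()

    def test_negative_counts_rejected(self, params):
        with pytest.raises(ValueError):
            detect_nonwear(np.array([0, -1, 0]), params)

    def test_matches_exhaustive_oracle_on_random_series(self, params):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(30, 220))
            counts = rng.choice([0, 0, 0, 0, 30, 120, 900], size=n)
            np.testing.assert_array_equal(
                detect_nonwear(counts, params), nonwear_oracle(counts, params)
            )


# ---------------------------------------------------------------------------
# sleep


def sleep_oracle(minutes, params):
    """Minute-by-minute recomputation of the linear sleep score."""
    sp = params.sleep
    n = len(minutes)
    half = sp.centered_window_min // 2
    padded = np.concatenate([np.zeros(half), minutes, np.zeros(half)])
    out = np.zeros(n, dtype=bool)
    for m in range(n):
        win = padded[m : m + sp.centered_window_min]
        avg = win.mean()
        nats = int(((win >= sp.nats_low) & (win < sp.nats_high)).sum())
        lo = max(0, m - (sp.trailing_window_min - 1))
        trail = np.concatenate(
            [np.zeros(sp.trailing_window_min - 1 - (m - lo)), minutes[lo : m + 1]]
        )
        sd = float(np.std(trail))
        lg = float(np.log(minutes[m] + 1))
        si = sp.intercept - sp.w_mean * avg - sp.w_nats * nats - sp.w_sd * sd - sp.w_log * lg
        out[m] = si >= sp.threshold
    return out


class TestScoreSleep:
    def test_overnight_zero_block_is_sleep(self, params):
        counts = np.zeros(8 * 60)
        assert score_sleep(counts, params).all()

    def test_sustained_high_activity_is_wake(self, params):
        counts = np.full(120, 3000.0)
        assert not score_sleep(counts, params).any()

    def test_short_series_rejected(self, params):
        with pytest.raises(ValueError):
            score_sleep(np.zeros(5), params)

    def test_overnight_window_forces_daytime_wake(self, params):
        counts = np.zeros(120)
        minute_of_day = np.arange(13 * 60, 15 * 60)  # 1-3 PM
        assert not score_sleep(counts, params, minute_of_day=minute_of_day).any()

    def test_matches_naive_recomputation(self, params):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(11, 200))
            counts = rng.choice([0, 0, 0, 10, 40, 75, 200, 1500], size=n).astype(float)
            np.testing.assert_array_equal(
                score_sleep(counts, params), sleep_oracle(counts, params)
            )


# ---------------------------------------------------------------------------
# intensity


class TestClassifyIntensity:
    def test_zero_is_sedentary(self):
        assert classify_intensity(np.array([0]), Cutpoints(), 5)[0] == 0

    def test_boundary_count_goes_to_higher_class(self):
        cp = Cutpoints()
        labels = classify_intensity(
            np.array([cp.light, cp.moderate, cp.vigorous]), cp, 5
        )
        np.testing.assert_array_equal(labels, [1, 2, 3])

    def test_unordered_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            Cutpoints(light=900, moderate=818, vigorous=1969)

    def test_aggregates_shorter_epochs_by_summation(self):
        cp = Cutpoints(native_epoch_s=10)
        fine = np.array([500, 500])  # 5 s epochs -> one 10 s epoch of 1000
        assert classify_intensity(fine, cp, 5)[0] == 2

    def test_incompatible_epoch_rejected(self):
        with pytest.raises(ValueError):
            classify_intensity(np.array([10]), Cutpoints(native_epoch_s=5), 60)

    @given(st.integers(0, 5000))
    @settings(deadline=None, derandomize=True)
    def test_matches_elementwise_thresholding(self, count):
        cp = Cutpoints()
        expected = (
            3 if count >= cp.vigorous else 2 if count >= cp.moderate
            else 1 if count >= cp.light else 0
        )
        assert classify_intensity(np.array([count]), cp, 5)[0] == expected


# ---------------------------------------------------------------------------
# day summary


def _flat_series(pid="P0", date="2017-04-03", minutes=1440, epoch_s=5, fill=100):
    per = 60 // epoch_s
    return EpochSeries(pid, pd.Timestamp(date), epoch_s, np.full(minutes * per, fill))


CAL = {pd.Timestamp("2017-04-03").date(): True}


class TestSummarizeDay:
    def test_constructed_evening_mvpa_block(self, params):
        series = _flat_series(fill=100)  # sedentary filler
        per = 60 // series.epoch_s
        counts = series.counts.copy()
        sl = slice(18 * 60 * per, 19 * 60 * per)  # 6-7 PM
        counts[sl] = 1000  # moderate
        series = EpochSeries("P0", series.start, 5, counts)
        n_min = 1440
        wear = np.zeros(n_min, bool)
        sleep = np.zeros(n_min, bool)
        labels = classify_intensity(series.counts, params.cutpoints, 5)
        s = summarize_day(series, wear, sleep, labels, CAL, params)
        assert s.mvpa_minutes == 60
        assert s.hourly_mvpa[18] == 60
        assert s.hourly_mvpa.sum() == 60
        assert s.wear_minutes == 1440

    def test_all_nonwear_day_invalid(self, params):
        series = _flat_series(fill=0)
        wear = np.ones(1440, bool)
        sleep = np.zeros(1440, bool)
        labels = classify_intensity(series.counts, params.cutpoints, 5)
        s = summarize_day(series, wear, sleep, labels, CAL, params)
        assert s.wear_minutes == 0 and not s.is_valid

    def test_missing_calendar_date_rejected(self, params):
        series = _flat_series(date="2020-01-01")
        with pytest.raises(ValueError, match="calendar"):
            summarize_day(
                series, np.zeros(1440, bool), np.zeros(1440, bool),
                np.zeros(1440 * 12, int), CAL, params,
            )

    def test_hourly_conservation_on_random_days(self, params):
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.choice([0, 100, 900, 1200, 2500], size=1440 * 12)
            series = EpochSeries("P0", pd.Timestamp("2017-04-03"), 5, counts)
            wear = rng.random(1440) < 0.2
            sleep = rng.random(1440) < 0.2
            labels = classify_intensity(series.counts, params.cutpoints, 5)
            s = summarize_day(series, wear, sleep, labels, CAL, params)
            assert np.isclose(s.hourly_mvpa.sum(), s.mvpa_minutes)
            # mask exclusivity: worn-awake minutes never overlap nonwear/sleep
            assert s.wear_minutes <= (~wear & ~sleep).sum()


# ---------------------------------------------------------------------------
# inclusion rules


def _day(pid, day, wear, date0="2017-04-01"):
    date = (pd.Timestamp(date0) + pd.Timedelta(days=day)).date()
    return DaySummary(
        participant_id=pid, date=date, wear_minutes=wear, mvpa_minutes=0.0,
        hourly_mvpa=np.zeros(24), hourly_wear=np.full(24, wear / 24),
        is_valid=wear >= 480, is_school_day=False,
    )


class TestInclusionRules:
    def test_wear_boundary_at_eight_hours_inclusive(self, params):
        days = [_day("A", d, 600) for d in range(3)]  # trimmed
        days += [_day("A", 3, 479), _day("A", 4, 480)]
        days += [_day("A", d, 600) for d in range(5, 9)]
        kept, log = apply_inclusion_rules(days, params)
        dates = {d.date for d in kept}
        assert _day("A", 3, 0).date not in dates  # 479 dropped
        assert _day("A", 4, 0).date in dates  # 480 kept
        rules = [e["rule"] for e in log]
        assert rules.count("min_wear") == 1

    def test_first_three_wear_days_trimmed(self, params):
        days = [_day("A", d, 700) for d in range(20)]
        kept, log = apply_inclusion_rules(days, params)
        kept_dates = sorted(d.date for d in kept)
        all_dates = sorted(d.date for d in days)
        assert kept_dates == all_dates[3:]
        assert sum(e["rule"] == "reactivity_trim" for e in log) == 3

    def test_participant_below_four_valid_days_excluded(self, params):
        days = [_day("B", d, 700) for d in range(6)]  # 3 left after trim
        kept, log = apply_inclusion_rules(days, params)
        assert kept == []
        assert any(e["rule"] == "min_valid_days" for e in log)

    def test_idempotent_on_own_output(self, params):
        rng = np.random.default_rng(3)
        days = [
            _day(f"P{p}", d, float(rng.choice([0, 300, 500, 700, 900])))
            for p in range(6)
            for d in range(12)
        ]
        kept1, _ = apply_inclusion_rules(days, params)
        kept2, log2 = apply_inclusion_rules(kept1, params)
        assert [(d.participant_id, d.date) for d in kept2] == [
            (d.participant_id, d.date) for d in kept1
        ]
        assert log2 == []

    def test_empty_input(self, params):
        kept, log = apply_inclusion_rules([], params)
        assert kept == [] and log == []
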