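"""Inactivity scoring, bout calling and per-day sleep metrics."""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flysleep.io_formats import annotate_phase
from flysleep.sleep_scoring import (
    asleep_mask,
    detect_bouts,
    inactivity_series,
    sleep_metrics,
    sleep_profile,
    waking_velocity,
)

from conftest import make_dam_trace, make_dart_trace

ZT0 = datetime(2018, 1, 1, 9, 0)


def brute_force_bouts(inactive, threshold):
    """Independent oracle: maximal runs of True with length >= threshold."""
    runs, start = [], None
    for i, v in enumerate(list(inactive) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= threshold:
                runs.append((start, i))
            start = None
    return runs


class TestInactivity:
    def test_dam_minute_inactive_iff_zero_counts(self):
        t = make_dam_trace([0, 0, 1, 0])
        assert list(inactivity_series(t)) == [True, True, False, True]

    def test_dart_minute_all_windows_sub_threshold(self):
        t = make_dart_trace([2.9] * 12)
        assert inactivity_series(t)[0]

    def test_dart_single_window_at_threshold_is_active(self):
        # "less than 3 mm" is strict: exactly 3.0 mm counts as movement
        t = make_dart_trace([2.9] * 11 + [3.0])
        assert not inactivity_series(t)[0]

    def test_dam_off_minute_grid_rejected(self):
        t = make_dam_trace([1, 2])
        t = t.with_values(t.values, bin_seconds=120)
        with pytest.raises(ValueError, match="1-min grid"):
            inactivity_series(t)


class TestDetectBouts:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ([1] * 5, [(0, 5)]),            # exactly at threshold
            ([1] * 4, []),                   # below threshold: no sleep
            ([1] * 10 + [0] + [1] * 6, [(0, 10), (11, 17)]),
        ],
    )
    def test_threshold_cases(self, pattern, expected):
        bouts = detect_bouts(np.asarray(pattern, bool))
        assert [(b.onset_bin, b.offset_bin) for b in bouts] == expected

    @given(st.lists(st.booleans(), min_size=1, max_size=24), st.integers(1, 6))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_enumeration(self, pattern, threshold):
        got = [(b.onset_bin, b.offset_bin) for b in detect_bouts(np.asarray(pattern), threshold)]
        assert got == brute_force_bouts(pattern, threshold)

    def test_min_bout_below_one_rejected(self):
        with pytest.raises(ValueError):
            detect_bouts(np.ones(5, bool), 0)


def _day_annotation(regime, n_min=1440):
    return annotate_phase(make_dam_trace(np.zeros(n_min), start=ZT0), regime)


class TestSleepMetrics:
    def test_bout_split_at_lights_off(self, regime_8l16d):
        # one bout ZT6-ZT10 straddles lights-off at ZT8: 120 min day, 120 night
        inactive = np.zeros(1440, bool)
        inactive[6 * 60 : 10 * 60] = True
        m = sleep_metrics(detect_bouts(inactive), _day_annotation(regime_8l16d), 1)
        assert m.day_sleep_min == 120 and m.night_sleep_min == 120
        assert m.bout_count_day == 1 and m.bout_count_night == 0  # onset phase

    def test_no_bouts_all_zero(self, regime_8l16d):
        m = sleep_metrics([], _day_annotation(regime_8l16d), 1)
        assert m.total_sleep_min == 0 and m.profile_30min.sum() == 0

    def test_hand_computed_schedule(self, regime_8l16d):
        # bouts (min): [60,120) day, [500,520) spans ZT8=480 boundary region
        inactive = np.zeros(1440, bool)
        inactive[60:120] = True
        inactive[470:520] = True
        inactive[1000:1004] = True  # 4-min run: not a bout
        ann = _day_annotation(regime_8l16d)
        m = sleep_metrics(detect_bouts(inactive), ann, 1)
        assert m.day_sleep_min == 60 + 10 and m.night_sleep_min == 40
        assert m.total_sleep_min == 110
        assert m.bout_count_day == 2 and m.bout_count_night == 0
        assert m.profile_30min.sum() == m.total_sleep_min

    def test_day_outside_recording_rejected(self, regime_8l16d):
        with pytest.raises(ValueError, match="day_index"):
            sleep_metrics([], _day_annotation(regime_8l16d), 5)

    def test_translation_by_whole_day_invariant(self, regime_8l16d):
        rng = np.random.default_rng(3)
        inactive = rng.random(1440) < 0.6
        ann1 = _day_annotation(regime_8l16d, 1440)
        two_day = np.r_[np.zeros(1440, bool), inactive]
        ann2 = _day_annotation(regime_8l16d, 2880)
        m1 = sleep_metrics(detect_bouts(inactive), ann1, 1)
        m2 = sleep_metrics(detect_bouts(two_day), ann2, 2)
        assert m1.total_sleep_min == m2.total_sleep_min
        assert m1.day_sleep_min == m2.day_sleep_min
        np.testing.assert_array_equal(m1.profile_30min, m2.profile_30min)


class TestProfile:
    def test_continuous_night_sleep(self, regime_8l16d):
        inactive = np.zeros(1440, bool)
        inactive[8 * 60 :] = True  # ZT8..ZT24
        ann = _day_annotation(regime_8l16d)
        bouts = detect_bouts(inactive)
        prof = sleep_profile(asleep_mask(1440, bouts), ann)
        assert all(prof[16:] == 30) and all(prof[:16] == 0)

    def test_lone_short_run_contributes_nothing(self, regime_8l16d):
        inactive = np.zeros(1440, bool)
        inactive[100:104] = True
        prof = sleep_profile(asleep_mask(1440, detect_bouts(inactive)), _day_annotation(regime_8l16d))
        assert prof.sum() == 0

    def test_partial_day_rejected(self, regime_8l16d):
        ann = _day_annotation(regime_8l16d, 1440)
        with pytest.raises(ValueError, match="full day"):
            sleep_profile(np.zeros(700, bool), ann)


class TestMonotonicity:
    @given(st.integers(0, 2**16 - 1))
    @settings(max_examples=60, deadline=None)
    def test_total_sleep_monotone_in_dart_threshold(self, bits):
        rng = np.random.default_rng(bits)
        mm = rng.gamma(1.5, 2.5, size=12 * 60)
        t = make_dart_trace(mm)
        totals = []
        for thr in (2.0, 3.0, 4.5):
            bouts = detect_bouts(inactivity_series(t, thr))
            totals.append(sum(b.duration_min for b in bouts))
        assert totals == sorted(totals)

    @given(st.integers(0, 2**16 - 1))
    @settings(max_examples=60, deadline=None)
    def test_total_sleep_monotone_in_bout_threshold(self, bits):
        rng = np.random.default_rng(bits)
        inactive = rng.random(240) < 0.5
        totals = [
            sum(b.duration_min for b in detect_bouts(inactive, k)) for k in (1, 3, 5, 8)
        ]
        assert totals == sorted(totals, reverse=True)


class TestWakingVelocity:
    def test_steady_walker(self):
        t = make_dart_trace([6.0] * 12 * 60)
        asleep = np.zeros(60, bool)
        wv = waking_velocity(t, asleep)
        assert wv.mean_mm_s == pytest.approx(1.2)  # 72 mm/min / 60 s

    def test_fully_asleep_bin_flagged_nan(self, regime_8l16d):
        t = make_dart_trace([0.0] * 12 * 1440, start=ZT0)
        asleep = np.ones(1440, bool)
        asleep[: 30] = False  # awake only in the first 30-min bin
        ann = annotate_phase(make_dam_trace(np.zeros(1440), start=ZT0), regime_8l16d)
        wv = waking_velocity(t, asleep, ann, 1)
        assert not np.isnan(wv.per_bin_mm_s[0])
        assert np.isnan(wv.per_bin_mm_s[1:]).all()

    def test_mixed_schedule_equals_hand_mean(self):
        rng = np.random.default_rng(9)
        mm = rng.gamma(2, 3, size=12 * 20)
        t = make_dart_trace(mm)
        asleep = rng.random(20) < 0.4
        wv = waking_velocity(t, asleep)
        per_min = mm.reshape(20, 12).sum(axis=1) / 60.0
        assert wv.mean_mm_s == pytest.approx(per_min[~asleep].mean())

    def test_dam_trace_rejected(self):
        with pytest.raises(ValueError, match="DART"):
            waking_velocity(make_dam_trace([1, 2]), np.zeros(2, bool))
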