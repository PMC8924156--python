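"""Behavioral scoring: nose-object distance, bout detection against a
brute-force run-enumeration oracle, DI identities and event onsets."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import norcircuit as nc
from norcircuit.behavior import (behavior_summary, detect_bouts,
                                 nose_object_distance, novel_event_onsets)
from norcircuit.core import ArenaObject, TrackingTrace


def _trace_with_nose(nose_xy, fs=25.0, objects=None):
    nose_xy = np.asarray(nose_xy, dtype=float)
    t = np.arange(len(nose_xy)) / fs
    return TrackingTrace(t, nose_xy.copy(), nose_xy,
                         objects=objects or [ArenaObject("novel", (15, 15))])


def bouts_bruteforce(t, dist, threshold=2.5):
    """Independent oracle: enumerate sub-threshold runs sample by sample."""
    runs, start = [], None
    for i, d in enumerate(dist):
        if d < threshold and start is None:
            start = i
        elif d >= threshold and start is not None:
            runs.append((t[start], t[i - 1]))
            start = None
    if start is not None:
        runs.append((t[start], t[len(dist) - 1]))
    return runs


class TestDistance:
    def test_nose_at_center_of_wide_object(self):
        trace = _trace_with_nose([[15, 15]],
                                 objects=[ArenaObject("novel", (15, 15), 5.0)])
        d = nose_object_distance(trace, trace.objects[0])
        assert d[0] == 0.0

    def test_surface_distance(self):
        trace = _trace_with_nose([[25, 15]],
                                 objects=[ArenaObject("novel", (15, 15), 5.0)])
        assert nose_object_distance(trace, trace.objects[0])[0] == 5.0

    def test_center_mode_flag(self):
        trace = _trace_with_nose([[25, 15]],
                                 objects=[ArenaObject("novel", (15, 15), 5.0)])
        d = nose_object_distance(trace, trace.objects[0], to_surface=False)
        assert d[0] == 10.0

    def test_matches_bruteforce_loop(self, rng):
        nose = rng.uniform(0, 75, (200, 2))
        obj = ArenaObject("novel", (30, 40), 5.0)
        trace = _trace_with_nose(nose, objects=[obj])
        d = nose_object_distance(trace, obj)
        for i in range(len(nose)):
            expect = max(np.hypot(nose[i, 0] - 30, nose[i, 1] - 40) - 5.0, 0.0)
            assert d[i] == pytest.approx(expect)


class TestDetectBouts:
    def test_constant_below_threshold_single_bout(self):
        t = np.arange(75) / 25.0
        bouts = detect_bouts(t, np.ones(75), "novel")
        assert len(bouts) == 1
        assert bouts[0].t_start == 0.0
        assert bouts[0].t_end == t[-1]

    def test_constant_above_threshold_no_bouts(self):
        t = np.arange(75) / 25.0
        assert detect_bouts(t, np.full(75, 5.0)) == []

    def test_two_runs_at_25hz(self):
        # sub-threshold on samples 10-19 and 40-44 -> bouts
        # [0.40, 0.76] s and [1.60, 1.76] s
        t = np.arange(50) / 25.0
        dist = np.full(50, 5.0)
        dist[10:20] = 1.0
        dist[40:45] = 1.0
        bouts = detect_bouts(t, dist, "novel")
        assert [(b.t_start, b.t_end) for b in bouts] == [
            pytest.approx((0.40, 0.76)), pytest.approx((1.60, 1.76))]

    def test_min_duration_filter(self):
        t = np.arange(50) / 25.0
        dist = np.full(50, 5.0)
        dist[10:20] = 1.0   # 0.36 s
        dist[40:42] = 1.0   # 0.04 s
        bouts = detect_bouts(t, dist, min_dur_s=0.1)
        assert len(bouts) == 1

    def test_matches_bruteforce_oracle(self, rng):
        t = np.arange(500) / 25.0
        dist = rng.uniform(0, 6, 500)
        got = [(b.t_start, b.t_end) for b in detect_bouts(t, dist)]
        assert got == pytest.approx(bouts_bruteforce(t, dist))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_bouts(np.array([]), np.array([]))


class TestSummary:
    def _summary(self, bouts):
        trace = _trace_with_nose(np.zeros((2, 2)))
        return behavior_summary(trace, bouts)

    def test_di_formula(self):
        s = self._summary([nc.ExplorationBout("novel", 0.0, 3.0),
                           nc.ExplorationBout("familiar", 5.0, 6.0)])
        assert s.di == pytest.approx(0.5)
        assert s.pct_novel == pytest.approx(75.0)

    def test_equal_times_zero_di(self):
        s = self._summary([nc.ExplorationBout("novel", 0.0, 2.0),
                           nc.ExplorationBout("familiar", 5.0, 7.0)])
        assert s.di == 0.0
        assert s.pct_novel == 50.0

    def test_no_exploration_is_missing_not_zero(self):
        s = self._summary([])
        assert np.isnan(s.di) and np.isnan(s.pct_novel)

    def test_stationary_animal_zero_distance(self):
        trace = _trace_with_nose(np.full((50, 2), 10.0))
        assert nc.total_distance(trace) == 0.0

    @given(st.lists(st.tuples(st.sampled_from(["novel", "familiar"]),
                              st.floats(0.01, 10.0)), min_size=1, max_size=20))
    def test_di_pct_identity(self, spec):
        # DI = 2*(pct/100) - 1 on arbitrary bout sets
        t0, bouts = 0.0, []
        for label, dur in spec:
            bouts.append(nc.ExplorationBout(label, t0, t0 + dur))
            t0 += dur + 1.0
        s = self._summary(bouts)
        assert s.di == pytest.approx(2 * (s.pct_novel / 100) - 1)

    def test_merging_abutting_bouts_invariant(self):
        a = self._summary([nc.ExplorationBout("novel", 0.0, 1.0),
                           nc.ExplorationBout("novel", 1.0, 3.0)])
        b = self._summary([nc.ExplorationBout("novel", 0.0, 3.0)])
        assert a.time_novel == b.time_novel
        assert a.di == b.di


class TestOnsets:
    def test_interleaved_filter_and_sort(self):
        bouts = [nc.ExplorationBout("familiar", 1.0, 2.0),
                 nc.ExplorationBout("novel", 12.0, 14.5),
                 nc.ExplorationBout("novel", 5.0, 6.0),
                 nc.ExplorationBout("familiar", 20.0, 21.0)]
        assert novel_event_onsets(bouts) == [5.0, 12.0]
        # independent filter-and-sort oracle
        assert novel_event_onsets(bouts) == sorted(
            b.t_start for b in bouts if b.object_label == "novel")

    def test_no_novel_bouts_empty(self):
        assert novel_event_onsets([nc.ExplorationBout("familiar", 0, 1)]) == []


class TestGroundTruthRecovery:
    def test_di_and_bout_count_recovered(self, tracking_session):
        params, trace, gt = tracking_session
        bouts = nc.detect_object_bouts(trace)
        s = behavior_summary(trace, bouts)
        assert s.di == pytest.approx(gt.di_true, abs=0.02)
        assert s.n_bouts_novel == len(gt.bouts["novel"])
        assert s.n_bouts_familiar == len(gt.bouts["familiar"])

    def test_bout_intervals_exact(self, tracking_session):
        _, trace, gt = tracking_session
        bouts = nc.detect_object_bouts(trace)
        got = [(b.t_start, b.t_end) for b in bouts if b.object_label == "novel"]
        assert got == pytest.approx(sorted(gt.bouts["novel"]))
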