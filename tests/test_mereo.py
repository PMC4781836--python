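import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placeschema.activity import ActivityInterval, CoactivityEvent
from placeschema.mereo_schema import (
    CoverRelation,
    MereologicalSchema,
    cover_relation_times,
    enumerate_candidates,
    surviving_timeline,
    update_cover,
)
from tests.conftest import make_trains


def iv(cell, start, end):
    return ActivityInterval(cell_id=cell, start=start, end=end)


def ev(window, cells):
    return CoactivityEvent(window=window, t_start=window * 0.25, cells=frozenset(cells))


class TestEnumerateCandidates:
    def test_shared_partner_creates_candidate(self):
        events = [ev(0, {1, 3}), ev(2, {2, 3})]
        cands = enumerate_candidates(events, n_cells=4)
        assert ((1, 2), 3) in cands

    def test_single_pair_event_insufficient(self):
        # each cell has only one coactivity partner: no pair bundles it
        assert enumerate_candidates([ev(0, {1, 2})], n_cells=3) == []

    def test_empty_events(self):
        assert enumerate_candidates([], n_cells=3) == []

    def test_candidates_deduplicated(self):
        events = [ev(0, {1, 3}), ev(2, {2, 3}), ev(4, {1, 2, 3})]
        cands = enumerate_candidates(events, n_cells=4)
        assert len(cands) == len(set(cands))


class TestCoverRelationTimes:
    def test_covered_interval_detected_never_violated(self):
        det, vio = cover_relation_times(
            [iv(0, 1.0, 2.0)], [iv(1, 0.0, 3.0)], [iv(2, 10.0, 11.0)], duration=20.0
        )
        assert det == pytest.approx(2.0)
        assert vio is None

    def test_later_uncovered_activity_violates(self):
        det, vio = cover_relation_times(
            [iv(0, 1.0, 2.0), iv(0, 5.0, 6.0)],
            [iv(1, 0.0, 3.0)],
            [iv(2, 10.0, 11.0)],
            duration=20.0,
        )
        assert det == pytest.approx(2.0)
        assert vio == pytest.approx(5.0)

    def test_uncovered_first_interval_delays_detection(self):
        # first interval not covered; second is: detection at the second
        det, vio = cover_relation_times(
            [iv(0, 1.0, 2.0), iv(0, 5.0, 6.0)],
            [iv(1, 4.5, 6.5)],
            [iv(2, 30.0, 31.0)],
            duration=40.0,
        )
        assert det == pytest.approx(6.0)
        assert vio is None

    def test_never_covered(self):
        det, vio = cover_relation_times(
            [iv(0, 1.0, 2.0)], [iv(1, 5.0, 6.0)], [iv(2, 7.0, 8.0)], duration=10.0
        )
        assert det is None and vio is None

    def test_joint_cover_by_both_members(self):
        # neither U cell alone covers V, their union does
        det, vio = cover_relation_times(
            [iv(0, 1.0, 3.0)], [iv(1, 0.5, 2.0)], [iv(2, 1.9, 3.5)], duration=10.0
        )
        assert det == pytest.approx(3.0)
        assert vio is None

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_covering_intervals(self, data):
        # enlarging U's intervals can only help detection and delay violation
        def draw_ivs(cell, k):
            out = []
            for _ in range(k):
                a = data.draw(st.floats(0, 18, allow_nan=False))
                w = data.draw(st.floats(0.1, 3, allow_nan=False))
                out.append(iv(cell, round(a, 2), round(min(a + w, 20), 2)))
            return sorted(out, key=lambda i: i.start)

        v = draw_ivs(0, data.draw(st.integers(1, 3)))
        u1 = draw_ivs(1, data.draw(st.integers(0, 2)))
        u2 = draw_ivs(2, data.draw(st.integers(0, 2)))
        det, vio = cover_relation_times(v, u1, u2, duration=20.0)
        pad = data.draw(st.floats(0, 2, allow_nan=False))
        u1_big = [iv(1, max(0.0, i.start - pad), min(20.0, i.end + pad)) for i in u1]
        det2, vio2 = cover_relation_times(v, u1_big, u2, duration=20.0)
        if det is not None:
            assert det2 is not None and det2 <= det
            if vio2 is not None:
                assert vio is not None and vio2 >= vio


class TestUpdateCoverAndTimeline:
    def test_update_fills_times(self):
        rels = [CoverRelation(u=(1, 2), v=0)]
        intervals = {0: [iv(0, 1, 2)], 1: [iv(1, 0, 3)], 2: []}
        update_cover(rels, intervals, t_end=10.0)
        assert rels[0].detected_at == pytest.approx(2.0)
        assert rels[0].violated_at is None

    def test_timeline_counts_alive_relations(self):
        rels = [CoverRelation(u=(1, 2), v=0, detected_at=10.0, violated_at=20.0)]
        tl = surviving_timeline(rels, np.array([5.0, 10.0, 15.0, 20.0, 25.0]))
        assert tl.tolist() == [0, 1, 1, 0, 0]

    def test_timeline_all_zero_without_relations(self):
        assert surviving_timeline([], np.array([1.0, 2.0])).tolist() == [0, 0]


class TestLearnerAgainstSweepOracle:
    def test_fit_matches_per_candidate_sweep(self):
        # random small session; the vectorized learner must agree with
        # the dense-grid sweep on every bundled candidate
        rng = np.random.default_rng(3)
        duration = 60.0
        spikes = {
            c: np.sort(rng.uniform(0, duration, rng.integers(5, 40)))
            for c in range(8)
        }
        trains = make_trains(spikes, duration=duration)
        learner = MereologicalSchema().fit(trains)
        from placeschema.activity import all_activity_intervals, coactivity_window
        from placeschema.graph_schema import build_graph
        from placeschema.activity import detect_coactivity

        window = coactivity_window(trains.theta_freq)
        intervals = all_activity_intervals(trains, window)
        events = detect_coactivity(trains, window)
        cands = enumerate_candidates(events, trains.n_cells)
        expected = {}
        for (u1, u2), v in cands:
            det, vio = cover_relation_times(
                intervals[v], intervals[u1], intervals[u2], duration, dt=0.01
            )
            if det is not None:
                expected[((u1, u2), v)] = (det, vio)
        got = {
            (r.u, r.v): (r.detected_at, r.violated_at) for r in learner.relations_
        }
        assert got.keys() == expected.keys()
        for key in expected:
            assert got[key][0] == pytest.approx(expected[key][0], abs=1e-9)
            if expected[key][1] is None:
                assert got[key][1] is None
            else:
                assert got[key][1] == pytest.approx(expected[key][1], abs=1e-9)

    def test_violated_set_only_grows(self):
        rng = np.random.default_rng(5)
        duration = 40.0
        spikes = {
            c: np.sort(rng.uniform(0, duration, rng.integers(10, 30)))
            for c in range(6)
        }
        learner = MereologicalSchema().fit(make_trains(spikes, duration=duration))
        times = np.linspace(0, duration, 30)
        violated = []
        for t in times:
            violated.append(
                sum(
                    1
                    for r in learner.relations_
                    if r.violated_at is not None and r.violated_at <= t
                )
            )
        assert all(a <= b for a, b in zip(violated, violated[1:]))
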