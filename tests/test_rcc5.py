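import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placeschema.activity import TemporalRelation
from placeschema.rcc5_schema import (
    COMPOSITION,
    CONTINUITY_EDGES,
    CONVERSE,
    RCC5_LABELS,
    RCC5Schema,
    RCC5State,
    count_inconsistencies,
    evidence_from_run,
    relation_counts_and_entropy,
    track_integrals,
    update_relation,
)
from tests.conftest import make_trains
from tests.oracles import count_inconsistencies_naive, rcc5_finite_model_composition


class TestEvidenceFromRun:
    @pytest.mark.parametrize(
        "rel,expected",
        [
            (TemporalRelation.SEPARATION, {"DR", "PO"}),
            (TemporalRelation.OVERLAP, {"PO"}),
            (TemporalRelation.DURING, {"PP", "PO"}),
            (TemporalRelation.INVERSE_DURING, {"PPi", "PO"}),
            (TemporalRelation.EQUAL, {"EQ", "PO"}),
        ],
    )
    def test_mapping(self, rel, expected):
        assert evidence_from_run(rel) == frozenset(expected)


class TestUpdateRelation:
    def test_overlap_moves_dr_to_po(self):
        state = RCC5State(n_cells=2)
        update_relation(state, (0, 1), TemporalRelation.OVERLAP, 1.0)
        assert state.label(0, 1) == "PO"

    def test_during_cannot_jump_to_containment(self):
        state = RCC5State(n_cells=2)
        update_relation(state, (0, 1), TemporalRelation.DURING, 1.0)
        assert state.label(0, 1) == "PO"  # not PP after a single run

    def test_unanimous_during_runs_reach_pp(self):
        state = RCC5State(n_cells=2, n_min=3)
        for k in range(3):
            update_relation(state, (0, 1), TemporalRelation.DURING, float(k))
        assert state.label(0, 1) == "PP"
        # history routed DR -> PO -> PP along continuity edges
        hist = state.history[(0, 1)]
        assert [(old, new) for _, old, new in hist] == [("DR", "PO"), ("PO", "PP")]

    def test_overlap_breaks_containment(self):
        state = RCC5State(n_cells=2, n_min=3)
        for k in range(3):
            update_relation(state, (0, 1), TemporalRelation.DURING, float(k))
        update_relation(state, (0, 1), TemporalRelation.OVERLAP, 5.0)
        assert state.label(0, 1) == "PO"

    def test_unanimous_equal_runs_reach_eq(self):
        state = RCC5State(n_cells=2, n_min=3)
        for k in range(3):
            update_relation(state, (0, 1), TemporalRelation.EQUAL, float(k))
        assert state.label(0, 1) == "EQ"

    def test_separation_only_keeps_dr(self):
        state = RCC5State(n_cells=2)
        update_relation(state, (0, 1), TemporalRelation.SEPARATION, 1.0)
        assert state.label(0, 1) == "DR"
        assert state.history.get((0, 1), []) == []

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(sorted(TemporalRelation, key=lambda r: r.value)),
                st.booleans(),
            ),
            max_size=12,
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_converse_and_continuity_invariants(self, runs):
        state = RCC5State(n_cells=2)
        for k, (rel, flip) in enumerate(runs):
            pair = (1, 0) if flip else (0, 1)
            update_relation(state, pair, rel, float(k))
        assert state.label(0, 1) == CONVERSE[state.label(1, 0)]
        for steps in state.history.values():
            for _, old, new in steps:
                assert frozenset({old, new}) in CONTINUITY_EDGES


class TestCompositionTable:
    def test_matches_finite_model_enumeration(self):
        assert COMPOSITION == rcc5_finite_model_composition()

    def test_paper_constraint_example(self):
        # x PO y and y PP z force x-z overlap and exclude z inside x
        allowed = COMPOSITION[("PO", "PP")]
        assert "DR" not in allowed and "PPi" not in allowed


class TestCountInconsistencies:
    def test_all_dr_is_consistent(self):
        assert count_inconsistencies(RCC5State(n_cells=4)) == 0

    def test_po_pp_dr_triple_flagged(self):
        state = RCC5State(n_cells=3)
        state.labels[(0, 1)] = "PO"
        state.labels[(1, 2)] = "PP"
        state.labels[(0, 2)] = "DR"
        assert count_inconsistencies(state) >= 1

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_triple_loop(self, data):
        n = 6
        state = RCC5State(n_cells=n)
        for i, j in itertools.combinations(range(n), 2):
            state.labels[(i, j)] = data.draw(st.sampled_from(RCC5_LABELS))
        naive = count_inconsistencies_naive(state.label, n, COMPOSITION)
        assert count_inconsistencies(state) == naive


class TestCountsAndEntropy:
    def test_all_dr_zero_entropy(self):
        counts, h = relation_counts_and_entropy(RCC5State(n_cells=5))
        assert counts["DR"] == 10 and h == 0.0

    def test_uniform_five_labels(self):
        state = RCC5State(n_cells=5)  # 10 pairs, two per label
        pairs = list(itertools.combinations(range(5), 2))
        for k, pair in enumerate(pairs):
            state.labels[pair] = RCC5_LABELS[k % 5]
        _, h = relation_counts_and_entropy(state)
        assert h == pytest.approx(np.log2(5), abs=1e-9)

    def test_three_dr_one_po_split(self):
        from placeschema.map_analysis import entropy_bits

        assert entropy_bits(["DR", "DR", "DR", "PO"]) == pytest.approx(0.8113, abs=1e-4)


class TestTrackIntegrals:
    @staticmethod
    def chain_state(n):
        state = RCC5State(n_cells=n)
        for i in range(n - 1):
            state.labels[(i, i + 1)] = "PO"
        return state

    def test_five_cell_chain(self):
        rep = track_integrals(self.chain_state(5))
        assert rep.count("endpoint") == 2
        assert rep.count("midpoint") == 3
        assert rep.count("junction") == 0

    def test_w_layout(self):
        # junction 0 overlaps midpoints 1,2,3; each midpoint its endpoint
        state = RCC5State(n_cells=7)
        for m, e in [(1, 4), (2, 5), (3, 6)]:
            state.labels[(0, m)] = "PO"
            state.labels[(min(m, e), max(m, e))] = "PO"
        rep = track_integrals(state)
        assert rep.count("junction") == 1
        assert rep.count("midpoint") == 3
        assert rep.count("endpoint") == 3

    def test_isolated_cell_unclassified(self):
        state = self.chain_state(3)
        state.n_cells = 4  # cell 3 has no relations
        rep = track_integrals(state)
        assert rep.classification[3] == "unclassified"


class TestLearner:
    @staticmethod
    def session(seed=0, n_cells=12, duration=120.0):
        rng = np.random.default_rng(seed)
        spikes = {}
        for c in range(n_cells):
            # bursty trains so intervals overlap across cells
            bursts = rng.uniform(0, duration, rng.integers(3, 8))
            times = np.concatenate([b + rng.uniform(0, 2.0, 12) for b in bursts])
            spikes[c] = np.sort(times[times < duration])
        return make_trains(spikes, duration=duration)

    def test_fit_produces_valid_state(self):
        learner = RCC5Schema().fit(self.session())
        state = learner.state_
        for (i, j), lab in state.labels.items():
            assert lab in RCC5_LABELS
            assert state.label(j, i) == CONVERSE[lab]
        for steps in state.history.values():
            for _, old, new in steps:
                assert frozenset({old, new}) in CONTINUITY_EDGES
        counts, h = relation_counts_and_entropy(state)
        assert sum(counts.values()) == state.n_cells * (state.n_cells - 1) // 2
        assert 0.0 <= h <= np.log2(5)

    def test_random_init_inconsistencies_decay(self):
        learner = RCC5Schema(init="random", seed=1, count_inconsistency=True).fit(
            self.session(seed=2)
        )
        assert learner.inconsistencies_final_ <= learner.inconsistencies_initial_

    def test_change_times_sorted_and_saturation_within_session(self):
        learner = RCC5Schema().fit(self.session(seed=3))
        assert np.all(np.diff(learner.change_times_) >= 0)
        assert 0.0 <= learner.t_n_ <= 120.0
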