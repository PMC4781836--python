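"""The RCC5 schema: qualitative region relations learned from spiking.

RCC5 relates two regions by one of five labels: DR (discrete), PO
(partial overlap), PP (proper part), PPi (inverse proper part), EQ
(equal).  Temporal relations between two cells' activity only
constrain the spatial relation: a temporal overlap certifies spatial
overlap, while separation, during and equality can all be produced by
a trajectory through partially overlapping fields.  The learner
therefore keeps, per pair, a best guess updated from accumulated
evidence, moving only along the RCC5 continuity graph
(DR–PO, PO–PP, PO–PPi, PO–EQ): a containment guess from a DR state
first passes through PO.

Evidence rule (per joint-activity run of a pair): any temporal-overlap
run forces PO; a containment label (PP/PPi/EQ) requires every joint
run so far to have shown during/equal and at least ``n_min`` such
runs; a pair with no joint runs is DR.  Violating triples of labels
are counted against the RCC5 composition table.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .activity import (
    ActivityInterval,
    TemporalRelation,
    all_activity_intervals,
    coactivity_window,
    temporal_relation,
)
from .graph_schema import saturation_time
from .place_cells import SpikeTrains

__all__ = [
    "RCC5_LABELS",
    "CONVERSE",
    "CONTINUITY_EDGES",
    "COMPOSITION",
    "RCC5State",
    "evidence_from_run",
    "update_relation",
    "count_inconsistencies",
    "relation_counts_and_entropy",
    "track_integrals",
    "RCC5Schema",
]

RCC5_LABELS = ("DR", "PO", "PP", "PPi", "EQ")

CONVERSE = {"DR": "DR", "PO": "PO", "PP": "PPi", "PPi": "PP", "EQ": "EQ"}

#: conceptual-neighborhood (continuity) edges: gradual deformation of two
#: regions can only move the relation along these
CONTINUITY_EDGES = frozenset(
    {frozenset({"DR", "PO"}), frozenset({"PO", "PP"}), frozenset({"PO", "PPi"}), frozenset({"PO", "EQ"})}
)

_ALL = frozenset(RCC5_LABELS)

#: RCC5 composition table: possible R(x,z) given R1(x,y) and R2(y,z)
COMPOSITION: dict[tuple[str, str], frozenset[str]] = {
    ("DR", "DR"): _ALL,
    ("DR", "PO"): frozenset({"DR", "PO", "PP"}),
    ("DR", "PP"): frozenset({"DR", "PO", "PP"}),
    ("DR", "PPi"): frozenset({"DR"}),
    ("DR", "EQ"): frozenset({"DR"}),
    ("PO", "DR"): frozenset({"DR", "PO", "PPi"}),
    ("PO", "PO"): _ALL,
    ("PO", "PP"): frozenset({"PO", "PP"}),
    ("PO", "PPi"): frozenset({"DR", "PO", "PPi"}),
    ("PO", "EQ"): frozenset({"PO"}),
    ("PP", "DR"): frozenset({"DR"}),
    ("PP", "PO"): frozenset({"DR", "PO", "PP"}),
    ("PP", "PP"): frozenset({"PP"}),
    ("PP", "PPi"): _ALL,
    ("PP", "EQ"): frozenset({"PP"}),
    ("PPi", "DR"): frozenset({"DR", "PO", "PPi"}),
    ("PPi", "PO"): frozenset({"PO", "PPi"}),
    ("PPi", "PP"): frozenset({"PO", "PP", "PPi", "EQ"}),
    ("PPi", "PPi"): frozenset({"PPi"}),
    ("PPi", "EQ"): frozenset({"PPi"}),
    ("EQ", "DR"): frozenset({"DR"}),
    ("EQ", "PO"): frozenset({"PO"}),
    ("EQ", "PP"): frozenset({"PP"}),
    ("EQ", "PPi"): frozenset({"PPi"}),
    ("EQ", "EQ"): frozenset({"EQ"}),
}

_TEMPORAL_TO_RCC5 = {
    TemporalRelation.SEPARATION: frozenset({"DR", "PO"}),
    TemporalRelation.OVERLAP: frozenset({"PO"}),
    TemporalRelation.DURING: frozenset({"PP", "PO"}),
    TemporalRelation.INVERSE_DURING: frozenset({"PPi", "PO"}),
    TemporalRelation.EQUAL: frozenset({"EQ", "PO"}),
}


def evidence_from_run(rel: TemporalRelation) -> frozenset[str]:
    """RCC5 labels consistent with one temporal relation between two
    cells' activity during a run through their fields."""
    return _TEMPORAL_TO_RCC5[TemporalRelation(rel)]


def _continuity_path(a: str, b: str) -> list[str]:
    """Shortest path in the continuity graph (PO is the hub)."""
    if a == b:
        return [a]
    if frozenset({a, b}) in CONTINUITY_EDGES:
        return [a, b]
    # all non-adjacent label pairs are bridged by PO
    return [a, "PO", b]


@dataclass
class _PairEvidence:
    joint_runs: int = 0
    overlap_runs: int = 0
    during_runs: int = 0
    inverse_during_runs: int = 0
    equal_runs: int = 0
    separation_runs: int = 0


@dataclass
class RCC5State:
    """Per-pair RCC5 best guesses with transition histories.

    Pairs are unordered; ``labels[(i, j)]`` with ``i < j`` holds the
    relation of i to j (PP means "i is a proper part of j").  The
    converse label is derived on query, so converse consistency holds
    by construction.
    """

    n_cells: int
    n_min: int = 3
    labels: dict[tuple[int, int], str] = field(default_factory=dict)
    history: dict[tuple[int, int], list[tuple[float, str, str]]] = field(default_factory=dict)
    evidence: dict[tuple[int, int], _PairEvidence] = field(default_factory=dict)

    @classmethod
    def random_init(cls, n_cells: int, seed: int | None = None, n_min: int = 3) -> "RCC5State":
        rng = np.random.default_rng(seed)
        state = cls(n_cells=n_cells, n_min=n_min)
        for i, j in itertools.combinations(range(n_cells), 2):
            state.labels[(i, j)] = RCC5_LABELS[int(rng.integers(5))]
        return state

    def label(self, i: int, j: int) -> str:
        if i == j:
            return "EQ"
        if i < j:
            return self.labels.get((i, j), "DR")
        return CONVERSE[self.labels.get((j, i), "DR")]

    def label_matrix(self) -> np.ndarray:
        """(n, n) array of label codes (indices into RCC5_LABELS)."""
        code = {lab: k for k, lab in enumerate(RCC5_LABELS)}
        m = np.zeros((self.n_cells, self.n_cells), dtype=np.int8)
        m[np.diag_indices(self.n_cells)] = code["EQ"]
        for (i, j), lab in self.labels.items():
            m[i, j] = code[lab]
            m[j, i] = code[CONVERSE[lab]]
        return m

    def _best_guess(self, ev: _PairEvidence, current: str) -> str:
        if ev.joint_runs == 0:
            return "DR" if ev.separation_runs > 0 else current
        if ev.overlap_runs > 0:
            return "PO"
        containment = ev.during_runs + ev.inverse_during_runs + ev.equal_runs
        if containment == ev.joint_runs and ev.joint_runs >= self.n_min:
            if ev.during_runs and not ev.inverse_during_runs:
                return "PP"
            if ev.inverse_during_runs and not ev.during_runs:
                return "PPi"
            if not ev.during_runs and not ev.inverse_during_runs:
                return "EQ"
        return "PO"

    def apply_evidence(self, i: int, j: int, rel: TemporalRelation, t: float) -> list[tuple[float, str, str]]:
        """Record one run's temporal relation for pair (i, j) and update
        the label along the continuity graph; returns the transitions."""
        if i == j:
            raise ValueError("pair must be two distinct cells")
        swap = i > j
        if swap:
            i, j = j, i
            rel = {
                TemporalRelation.DURING: TemporalRelation.INVERSE_DURING,
                TemporalRelation.INVERSE_DURING: TemporalRelation.DURING,
            }.get(TemporalRelation(rel), TemporalRelation(rel))
        key = (i, j)
        ev = self.evidence.setdefault(key, _PairEvidence())
        rel = TemporalRelation(rel)
        if rel is TemporalRelation.SEPARATION:
            ev.separation_runs += 1
        else:
            ev.joint_runs += 1
            if rel is TemporalRelation.OVERLAP:
                ev.overlap_runs += 1
            elif rel is TemporalRelation.DURING:
                ev.during_runs += 1
            elif rel is TemporalRelation.INVERSE_DURING:
                ev.inverse_during_runs += 1
            else:
                ev.equal_runs += 1
        current = self.labels.get(key, "DR")
        target = self._best_guess(ev, current)
        steps: list[tuple[float, str, str]] = []
        if target != current:
            path = _continuity_path(current, target)
            for old, new in zip(path[:-1], path[1:]):
                steps.append((t, old, new))
            self.labels[key] = target
            self.history.setdefault(key, []).extend(steps)
        return steps


def update_relation(state: RCC5State, pair: tuple[int, int], rel: TemporalRelation, t: float) -> RCC5State:
    """Functional wrapper around :meth:`RCC5State.apply_evidence`."""
    state.apply_evidence(pair[0], pair[1], rel, t)
    return state


def count_inconsistencies(state: RCC5State) -> int:
    """Ordered triples (x, y, z) of distinct cells whose labels violate
    the RCC5 composition table."""
    if state.n_cells < 3:
        raise ValueError("need at least three cells")
    m = state.label_matrix()
    code = {lab: k for k, lab in enumerate(RCC5_LABELS)}
    n = state.n_cells
    offdiag = ~np.eye(n, dtype=bool)
    indicators = {}
    for lab, k in code.items():
        a = (m == k) & offdiag
        indicators[k] = a
    total = 0
    for a_lab, a_k in code.items():
        A = indicators[a_k].astype(np.int64)
        for b_lab, b_k in code.items():
            allowed = COMPOSITION[(a_lab, b_lab)]
            forbidden = [code[c] for c in RCC5_LABELS if c not in allowed]
            if not forbidden:
                continue
            P = A @ indicators[b_k].astype(np.int64)
            for c_k in forbidden:
                total += int(P[indicators[c_k]].sum())
    return total


def relation_counts_and_entropy(state: RCC5State) -> tuple[dict[str, int], float]:
    """Counts of the five labels over all unordered pairs, and the
    entropy (bits) of their frequency distribution."""
    total = state.n_cells * (state.n_cells - 1) // 2
    counts = {lab: 0 for lab in RCC5_LABELS}
    for lab in state.labels.values():
        counts[lab] += 1
    counts["DR"] += total - len(state.labels)
    h = 0.0
    for c in counts.values():
        if c > 0:
            p = c / total
            h -= p * np.log2(p)
    return counts, float(h)


@dataclass
class TrackIntegralReport:
    overlap_degree: dict[int, int]
    classification: dict[int, str]
    stabilized_at: dict[int, float]

    def count(self, kind: str) -> int:
        return sum(1 for v in self.classification.values() if v == kind)

    def integral_stabilization_time(self) -> float:
        """Latest time an endpoint or junction classification changed to
        its final value (s)."""
        ts = [
            self.stabilized_at[c]
            for c, kind in self.classification.items()
            if kind in ("endpoint", "junction")
        ]
        return max(ts, default=0.0)


def _classify(degree: int) -> str:
    if degree == 0:
        return "unclassified"
    if degree == 1:
        return "endpoint"
    if degree == 2:
        return "midpoint"
    return "junction"


def track_integrals(state: RCC5State) -> TrackIntegralReport:
    """Endpoint/midpoint/junction classification of each cell from its
    count of non-DR partners, with the time each classification
    stabilized (last change of the cell's classification)."""
    degree = {c: 0 for c in range(state.n_cells)}
    for (i, j), lab in state.labels.items():
        if lab != "DR":
            degree[i] += 1
            degree[j] += 1
    classification = {c: _classify(d) for c, d in degree.items()}

    # replay label histories to find when each classification last changed
    events: list[tuple[float, int, int]] = []  # (t, cell, degree delta)
    for (i, j), steps in state.history.items():
        for t, old, new in steps:
            delta = (new != "DR") - (old != "DR")
            if delta:
                events.append((t, i, delta))
                events.append((t, j, delta))
    events.sort(key=lambda e: e[0])
    deg_now = {c: 0 for c in range(state.n_cells)}
    cls_now = {c: _classify(0) for c in range(state.n_cells)}
    stabilized = {c: 0.0 for c in range(state.n_cells)}
    for t, cell, delta in events:
        deg_now[cell] += delta
        new_cls = _classify(deg_now[cell])
        if new_cls != cls_now[cell]:
            cls_now[cell] = new_cls
            stabilized[cell] = t
    return TrackIntegralReport(overlap_degree=degree, classification=classification,
                               stabilized_at=stabilized)


# ---------------------------------------------------------------------------
# learner
# ---------------------------------------------------------------------------

def _pair_episodes(
    a: list[ActivityInterval], b: list[ActivityInterval], tol: float
) -> list[tuple[float, TemporalRelation]]:
    """Joint-activity episodes of two cells: connected components of the
    union of their intervals that contain activity of both, each labeled
    with the temporal relation of the two cells' spans and stamped with
    the episode end time."""
    items = sorted(
        [(iv.start, iv.end, 0) for iv in a] + [(iv.start, iv.end, 1) for iv in b]
    )
    episodes: list[tuple[float, TemporalRelation]] = []
    cur: list[tuple[float, float, int]] = []
    cur_end = -np.inf

    def close() -> None:
        spans = {}
        for s, e, who in cur:
            lo, hi = spans.get(who, (np.inf, -np.inf))
            spans[who] = (min(lo, s), max(hi, e))
        if len(spans) == 2:
            ia = ActivityInterval(cell_id=0, start=spans[0][0], end=spans[0][1])
            ib = ActivityInterval(cell_id=1, start=spans[1][0], end=spans[1][1])
            rel = temporal_relation(ia, ib, tol)
            if rel is TemporalRelation.OVERLAP:
                shared = min(ia.end, ib.end) - max(ia.start, ib.start)
                # a contact shorter than the relation tolerance is below
                # the model's temporal resolution: not evidence of overlap
                if shared < tol:
                    rel = TemporalRelation.SEPARATION
            episodes.append((cur_end, rel))

    for s, e, who in items:
        if cur and s > cur_end:
            close()
            cur = []
            cur_end = -np.inf
        cur.append((s, e, who))
        cur_end = max(cur_end, e)
    if cur:
        close()
    return episodes


class RCC5Schema(BaseEstimator):
    """Learner for the RCC5 relational schema.

    Parameters
    ----------
    n_min :
        Minimum number of unanimous during/equal joint runs before a
        containment label (PP/PPi/EQ) is adopted.
    init :
        ``"dr"`` starts every pair at DR; ``"random"`` draws uniform
        labels (the inconsistency-decay experiment).

    Attributes (after :meth:`fit`)
    ------------------------------
    state_ : RCC5State
    counts_, entropy_ : final label distribution and its entropy (bits)
    change_times_ : sorted times of all label transitions
    t_n_ : saturation time of cumulative relation changes (s)
    inconsistencies_initial_, inconsistencies_final_ : composition-table
        violations before and after learning (random init only for the
        former to be nonzero)
    """

    def __init__(self, n_min: int = 3, init: str = "dr", seed: int | None = None,
                 window: float | None = None, tail_tolerance: float = 0.01,
                 count_inconsistency: bool = False):
        self.n_min = n_min
        self.init = init
        self.seed = seed
        self.window = window
        self.tail_tolerance = tail_tolerance
        self.count_inconsistency = count_inconsistency

    def fit(self, trains: SpikeTrains, y=None):
        window = self.window or coactivity_window(trains.theta_freq)
        tol = window / 2.0
        intervals = all_activity_intervals(trains, window)
        if self.init == "random":
            state = RCC5State.random_init(trains.n_cells, seed=self.seed, n_min=self.n_min)
        else:
            state = RCC5State(n_cells=trains.n_cells, n_min=self.n_min)
        if self.count_inconsistency:
            self.inconsistencies_initial_ = count_inconsistencies(state)

        # pairs whose intervals ever intersect, via a sweep over all intervals
        items = sorted(
            (iv.start, iv.end, cid)
            for cid, ivs in intervals.items()
            for iv in ivs
        )
        joint_pairs: set[tuple[int, int]] = set()
        active: list[tuple[float, int]] = []  # heap of (end, cell)
        for s, e, cid in items:
            while active and active[0][0] < s:
                heapq.heappop(active)
            for _, other in active:
                if other != cid:
                    joint_pairs.add((min(cid, other), max(cid, other)))
            heapq.heappush(active, (e, cid))

        # evidence stream: joint episodes per pair + one separation event
        # per pair of ever-active cells (the first run past one field
        # without the other); later separations cannot change a label
        first_end = {
            cid: ivs[0].end for cid, ivs in intervals.items() if ivs
        }
        events: list[tuple[float, int, int, TemporalRelation]] = []
        for i, j in joint_pairs:
            for t, rel in _pair_episodes(intervals[i], intervals[j], tol):
                events.append((t, i, j, rel))
        active_cells = sorted(first_end)
        for a_idx in range(len(active_cells)):
            for b_idx in range(a_idx + 1, len(active_cells)):
                i, j = active_cells[a_idx], active_cells[b_idx]
                t = min(first_end[i], first_end[j])
                events.append((t, i, j, TemporalRelation.SEPARATION))
        events.sort(key=lambda ev: ev[0])

        changes: list[float] = []
        for t, i, j, rel in events:
            steps = state.apply_evidence(i, j, rel, t)
            changes.extend(s[0] for s in steps)

        self.state_ = state
        self.change_times_ = np.sort(np.array(changes))
        self.t_n_ = saturation_time(
            self.change_times_, np.arange(1, len(self.change_times_) + 1),
            self.tail_tolerance,
        ) if len(self.change_times_) else 0.0
        self.counts_, self.entropy_ = relation_counts_and_entropy(state)
        if self.count_inconsistency:
            self.inconsistencies_final_ = count_inconsistencies(state)
        self.duration_ = trains.duration
        return self

    def counts_timeline(self, times: np.ndarray) -> dict[str, np.ndarray]:
        """Per-label pair counts at each probe time, replayed from the
        transition histories."""
        events: list[tuple[float, str, str]] = []
        for steps in self.state_.history.values():
            events.extend(steps)
        events.sort(key=lambda e: e[0])
        total = self.state_.n_cells * (self.state_.n_cells - 1) // 2
        counts = {lab: 0 for lab in RCC5_LABELS}
        counts["DR"] = total
        out = {lab: np.empty(len(times), dtype=int) for lab in RCC5_LABELS}
        times = np.asarray(times, float)
        k = 0
        for ti, t in enumerate(times):
            while k < len(events) and events[k][0] <= t:
                _, old, new = events[k]
                counts[old] -= 1
                counts[new] += 1
                k += 1
            for lab in RCC5_LABELS:
                out[lab][ti] = counts[lab]
        return out

    def track_report(self) -> TrackIntegralReport:
        return track_integrals(self.state_)

    def report(self) -> dict:
        return {
            "counts": self.counts_,
            "entropy_bits": self.entropy_,
            "t_n_s": self.t_n_,
            "n_changes": int(len(self.change_times_)),
        }


def write_relation_matrix(state: RCC5State, path) -> None:
    rows = []
    for (i, j), lab in sorted(state.labels.items()):
        hist = state.history.get((i, j), [])
        rows.append({"i": i, "j": j, "label": lab,
                     "t_last_change": hist[-1][0] if hist else None})
    pd.DataFrame(rows, columns=["i", "j", "label", "t_last_change"]).to_csv(path, index=False)
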