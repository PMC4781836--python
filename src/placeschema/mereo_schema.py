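"""The mereological schema: temporal cover relations.

A pair of cells U = {c_i, c_j} *covers* a cell V = {d} when V's activity
happens only while at least one member of U is active — the spatial
reading is that V's field lies inside the union of U's fields.  The
associated readout neuron (excitation from V, inhibition from U) stays
silent as long as the cover holds; its first spike marks a permanent
violation.

A relation is *detected* at the end of the first activity interval of V
that is fully contained in the union of U's activity intervals, and
*violated* at the first later moment V is active outside that union.
Candidates are restricted to "bundled" triples — V must have cofired
with both members of U at least once — keeping the O(N^3) candidate
space tractable.

All containment tests are evaluated on the trajectory's dt time grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .activity import (
    ActivityInterval,
    CoactivityEvent,
    all_activity_intervals,
    coactivity_window,
    detect_coactivity,
)
from .graph_schema import build_graph, saturation_time
from .place_cells import SpikeTrains

__all__ = [
    "CoverRelation",
    "enumerate_candidates",
    "cover_relation_times",
    "update_cover",
    "surviving_timeline",
    "MereologicalSchema",
]


@dataclass
class CoverRelation:
    u: tuple[int, int]  # covering pair
    v: int  # covered cell
    detected_at: float | None = None
    violated_at: float | None = None

    def __post_init__(self) -> None:
        if self.v in self.u:
            raise ValueError("covered cell must not belong to the covering pair")

    def alive_at(self, t: float) -> bool:
        return (
            self.detected_at is not None
            and self.detected_at <= t
            and (self.violated_at is None or self.violated_at > t)
        )


def enumerate_candidates(events: list[CoactivityEvent], n_cells: int) -> list[tuple[tuple[int, int], int]]:
    """Candidate (U, V) triples: V has cofired with both members of U."""
    graph = build_graph(events, n_cells)
    neighbors: dict[int, set[int]] = {}
    for i, j in graph.edge_times:
        neighbors.setdefault(i, set()).add(j)
        neighbors.setdefault(j, set()).add(i)
    out = []
    for d in sorted(neighbors):
        nb = sorted(neighbors[d])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                out.append(((nb[a], nb[b]), d))
    return out


def _grid_mask(intervals: list[ActivityInterval], n: int, dt: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for iv in intervals:
        lo = max(0, int(math.ceil(iv.start / dt - 1e-9)))
        hi = min(n - 1, int(math.floor(iv.end / dt + 1e-9)))
        if hi >= lo:
            mask[lo : hi + 1] = True
    return mask


def cover_relation_times(
    v_intervals: list[ActivityInterval],
    u1_intervals: list[ActivityInterval],
    u2_intervals: list[ActivityInterval],
    duration: float,
    dt: float = 0.01,
) -> tuple[float | None, float | None]:
    """Detection and violation times of one cover candidate, evaluated
    by a sweep on the dt grid.  Returns ``(detected_at, violated_at)``,
    either of which may be None.
    """
    n = int(round(duration / dt)) + 1
    v_mask = _grid_mask(v_intervals, n, dt)
    u_mask = _grid_mask(u1_intervals, n, dt) | _grid_mask(u2_intervals, n, dt)
    uncovered = v_mask & ~u_mask
    # reconstruct V's runs on the grid
    padded = np.concatenate([[False], v_mask, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    detected_at = None
    detect_end = None
    for s, e in zip(starts, ends):
        if not uncovered[s : e + 1].any():
            detected_at, detect_end = e * dt, e
            break
    if detected_at is None:
        return None, None
    later = np.flatnonzero(uncovered[detect_end + 1 :])
    violated_at = float((detect_end + 1 + later[0]) * dt) if len(later) else None
    return float(detected_at), violated_at


def update_cover(
    relations: list[CoverRelation],
    intervals: dict[int, list[ActivityInterval]],
    t_end: float,
    dt: float = 0.01,
) -> list[CoverRelation]:
    """Fill detection/violation times for each candidate relation from
    the cells' activity-interval families (causal sweep to ``t_end``)."""
    for rel in relations:
        det, vio = cover_relation_times(
            intervals.get(rel.v, []),
            intervals.get(rel.u[0], []),
            intervals.get(rel.u[1], []),
            t_end,
            dt,
        )
        rel.detected_at, rel.violated_at = det, vio
    return relations


def surviving_timeline(relations: list[CoverRelation], times: np.ndarray) -> np.ndarray:
    """Number of detected, not-yet-violated relations at each probe time."""
    det = np.array([r.detected_at for r in relations if r.detected_at is not None])
    vio = np.array(
        [r.violated_at if r.violated_at is not None else np.inf
         for r in relations if r.detected_at is not None]
    )
    times = np.asarray(times, float)
    out = np.empty(len(times), dtype=int)
    for k, t in enumerate(times):
        out[k] = int(np.sum((det <= t) & (vio > t)))
    return out


class MereologicalSchema(BaseEstimator):
    """Learner for pair-covers-single mereological relations.

    The fit is a vectorized equivalent of running
    :func:`cover_relation_times` over every bundled candidate triple.

    Attributes (after :meth:`fit`)
    ------------------------------
    relations_ : list[CoverRelation] (detected ones only)
    n_candidates_ : number of bundled candidate triples
    n_detected_, n_surviving_ : counts at session end
    majority_violation_time_ : earliest time by which more than half of
        all relations ever detected have been violated (None if never)
    """

    def __init__(self, window: float | None = None, dt: float = 0.01):
        self.window = window
        self.dt = dt

    def fit(self, trains: SpikeTrains, y=None):
        dt = self.dt
        window = self.window or coactivity_window(trains.theta_freq)
        events = detect_coactivity(trains, window)
        intervals = all_activity_intervals(trains, window)
        n = int(round(trains.duration / dt)) + 1

        cell_ids = sorted(trains.times)
        act = {cid: _grid_mask(intervals[cid], n, dt) for cid in cell_ids}

        graph = build_graph(events, trains.n_cells)
        neighbors: dict[int, set[int]] = {}
        for i, j in graph.edge_times:
            neighbors.setdefault(i, set()).add(j)
            neighbors.setdefault(j, set()).add(i)

        relations: list[CoverRelation] = []
        n_candidates = 0
        for d in sorted(neighbors):
            nb = sorted(neighbors[d])
            if not nb:
                continue
            idx_d = np.flatnonzero(act[d])
            if len(idx_d) == 0:
                n_candidates += len(nb) * (len(nb) - 1) // 2
                continue
            # V's runs as offset ranges in the compressed (active-sample) axis
            run_breaks = np.flatnonzero(np.diff(idx_d) > 1)
            run_starts = np.concatenate([[0], run_breaks + 1])
            run_ends = np.concatenate([run_breaks, [len(idx_d) - 1]])
            unc = {i: ~act[i][idx_d] for i in nb}
            for a in range(len(nb)):
                ua = unc[nb[a]]
                for b in range(a + 1, len(nb)):
                    n_candidates += 1
                    u = ua & unc[nb[b]]
                    nz = np.flatnonzero(u)
                    if len(nz) == 0:
                        # every run covered: detected at end of first run
                        relations.append(
                            CoverRelation(
                                u=(nb[a], nb[b]), v=d,
                                detected_at=float(idx_d[run_ends[0]] * dt),
                            )
                        )
                        continue
                    cnt = np.searchsorted(nz, run_ends, side="right") - np.searchsorted(nz, run_starts)
                    covered = np.flatnonzero(cnt == 0)
                    if len(covered) == 0:
                        continue  # never detected
                    k = covered[0]
                    det = float(idx_d[run_ends[k]] * dt)
                    later = nz[np.searchsorted(nz, run_ends[k], side="right"):]
                    vio = float(idx_d[later[0]] * dt) if len(later) else None
                    relations.append(CoverRelation(u=(nb[a], nb[b]), v=d,
                                                   detected_at=det, violated_at=vio))

        self.relations_ = relations
        self.n_candidates_ = n_candidates
        self.n_detected_ = len(relations)
        self.n_surviving_ = sum(1 for r in relations if r.violated_at is None)
        vio_times = np.sort([r.violated_at for r in relations if r.violated_at is not None])
        need = len(relations) // 2 + 1  # strictly more than half
        self.majority_violation_time_ = (
            float(vio_times[need - 1]) if len(vio_times) >= need else None
        )
        self.duration_ = trains.duration
        return self

    def timeline(self, times: np.ndarray) -> np.ndarray:
        return surviving_timeline(self.relations_, times)

    def report(self) -> dict:
        return {
            "n_candidates": self.n_candidates_,
            "n_detected": self.n_detected_,
            "n_surviving": self.n_surviving_,
            "majority_violation_time_s": self.majority_violation_time_,
        }


def write_relations(relations: list[CoverRelation], path) -> None:
    pd.DataFrame(
        {
            "u1": [r.u[0] for r in relations],
            "u2": [r.u[1] for r in relations],
            "v": [r.v for r in relations],
            "t_detected": [r.detected_at for r in relations],
            "t_violated": [r.violated_at for r in relations],
        }
    ).to_csv(path, index=False)
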