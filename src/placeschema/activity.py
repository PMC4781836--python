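"""From point spikes to activity intervals, coactivity events and
qualitative temporal relations.

Coactivity is defined on a tiling of the session into consecutive
windows of two theta periods (~250 ms at 8 Hz): cells that each emit at
least one spike inside the same window are coactive.  Activity
*intervals* are maximal runs of spikes with inter-spike gaps no larger
than a merge gap (default: the coactivity window), padded by half the
gap on each side — the rate-based notion of "the period of activity of
a neuron".

Interval pairs are classified into five qualitative temporal
relations: separation, overlap, during, inverse-during, equal —
the interval-algebra vocabulary used by the RCC5 learner.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .place_cells import SpikeTrains

__all__ = [
    "ActivityInterval",
    "CoactivityEvent",
    "TemporalRelation",
    "coactivity_window",
    "detect_coactivity",
    "activity_intervals",
    "all_activity_intervals",
    "temporal_relation",
    "write_events",
]


class TemporalRelation(str, Enum):
    SEPARATION = "separation"
    OVERLAP = "overlap"
    DURING = "during"
    INVERSE_DURING = "inverse-during"
    EQUAL = "equal"


@dataclass(frozen=True)
class ActivityInterval:
    cell_id: int
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("interval end must be >= start")


@dataclass(frozen=True)
class CoactivityEvent:
    """All cells with at least one spike in one coactivity window."""

    window: int
    t_start: float
    cells: frozenset[int]


def coactivity_window(theta_freq: float) -> float:
    """Length of the coactivity window: two theta periods (s)."""
    if theta_freq <= 0:
        raise ValueError("theta frequency must be positive")
    return 2.0 / theta_freq


def detect_coactivity(trains: SpikeTrains, window: float | None = None) -> list[CoactivityEvent]:
    """Tile the session into consecutive windows and report, per window,
    the set of cells with at least one spike; windows with fewer than
    two active cells are omitted.
    """
    if window is None:
        window = coactivity_window(trains.theta_freq)
    if window <= 0:
        raise ValueError("window must be positive")
    active: dict[int, set[int]] = {}
    for cid, t in trains.times.items():
        if len(t) == 0:
            continue
        for w in np.unique((t / window).astype(int)):
            active.setdefault(int(w), set()).add(cid)
    events = [
        CoactivityEvent(window=w, t_start=w * window, cells=frozenset(cells))
        for w, cells in sorted(active.items())
        if len(cells) >= 2
    ]
    return events


def activity_intervals(
    spike_times: np.ndarray, merge_gap: float, cell_id: int = -1,
    t_max: float | None = None,
) -> list[ActivityInterval]:
    """Merge spikes separated by at most ``merge_gap`` into maximal runs,
    padded by ``merge_gap/2`` on each side (clipped to ``[0, t_max]``).
    """
    if merge_gap <= 0:
        raise ValueError("merge_gap must be positive")
    t = np.asarray(spike_times, float)
    if len(t) == 0:
        return []
    t = np.sort(t)
    breaks = np.flatnonzero(np.diff(t) > merge_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(t) - 1]])
    half = merge_gap / 2.0
    out = []
    for a, b in zip(starts, ends):
        lo = max(0.0, t[a] - half)
        hi = t[b] + half
        if t_max is not None:
            hi = min(hi, t_max)
        out.append(ActivityInterval(cell_id=cell_id, start=lo, end=hi))
    return out


def all_activity_intervals(trains: SpikeTrains, merge_gap: float | None = None) -> dict[int, list[ActivityInterval]]:
    """Activity intervals for every cell of a spike-train bundle."""
    if merge_gap is None:
        merge_gap = coactivity_window(trains.theta_freq)
    return {
        cid: activity_intervals(t, merge_gap, cell_id=cid, t_max=trains.duration)
        for cid, t in trains.times.items()
    }


def temporal_relation(a: ActivityInterval, b: ActivityInterval, tol: float = 0.01) -> TemporalRelation:
    """Classify the qualitative temporal relation of two intervals.

    Separation if they are disjoint; equal if both endpoints agree
    within ``tol``; during (inverse-during) if one lies inside the
    other up to ``tol``; overlap otherwise.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    if a.end < b.start or b.end < a.start:
        return TemporalRelation.SEPARATION
    if abs(a.start - b.start) <= tol and abs(a.end - b.end) <= tol:
        return TemporalRelation.EQUAL
    if a.start >= b.start - tol and a.end <= b.end + tol:
        return TemporalRelation.DURING
    if b.start >= a.start - tol and b.end <= a.end + tol:
        return TemporalRelation.INVERSE_DURING
    return TemporalRelation.OVERLAP


def write_events(events: list[CoactivityEvent], path) -> None:
    pd.DataFrame(
        {
            "window_index": [e.window for e in events],
            "t_start": [e.t_start for e in events],
            "cell_ids": ["|".join(str(c) for c in sorted(e.cells)) for e in events],
        }
    ).to_csv(path, index=False)
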