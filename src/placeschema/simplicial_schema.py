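"""The higher-order coactivity (simplicial) schema.

Every coactivity event of k cells is a (k-1)-dimensional simplex.  The
schema stores only *maximal* simplexes: an incoming event already
contained in a stored simplex is redundant and ignored; a stored
simplex contained in an incoming event is removed (its readout neuron
is replaced by a higher-order coincidence detector).  The stored
family is therefore an antichain at all times, while the implied face
set — and hence the homology of the complex — only ever grows.

Topological integrals are computed from the insertion log: Betti
numbers, the persistence barcode of the detection-time filtration, and
the topological learning time T_min (the death of the last spurious
loop), after which the complex holds the homotopy signature of the
environment (for the standard arena: one connected component and one
1-loop around the central hole).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .activity import CoactivityEvent, coactivity_window, detect_coactivity
from .graph_schema import saturation_time
from .homology import Barcode, betti_from_maximal, persistence_from_log, topological_learning_time
from .place_cells import SpikeTrains

__all__ = [
    "CoactivityComplex",
    "insert_coactivity",
    "order_histogram",
    "betti_numbers",
    "barcodes",
    "topological_learning_time",
    "SimplicialSchema",
]


@dataclass
class CoactivityComplex:
    """Antichain of maximal coactivity simplexes with detection times.

    ``log`` records every structure-changing insertion (time, cells),
    including those later absorbed into larger simplexes; absorbed
    simplexes stay part of the complex as faces, so the filtration is
    monotone.
    """

    maximal: dict[frozenset[int], float] = field(default_factory=dict)
    log: list[tuple[float, frozenset[int]]] = field(default_factory=list)
    _by_vertex: dict[int, set[frozenset[int]]] = field(default_factory=dict, repr=False)

    @property
    def n_maximal(self) -> int:
        return len(self.maximal)

    @property
    def vertices(self) -> set[int]:
        return set(self._by_vertex)

    def max_order(self) -> int:
        return max((len(s) for s in self.maximal), default=0)

    def insert(self, cells, t: float) -> bool:
        """Insert a coactivity; returns True if the complex changed."""
        cells = frozenset(cells)
        if not cells:
            raise ValueError("cannot insert an empty cell set")
        # redundant if contained in an existing maximal simplex
        probe = min(
            (self._by_vertex.get(v, ()) for v in cells),
            key=len,
            default=(),
        )
        for m in probe:
            if cells <= m:
                return False
        # remove stored simplexes that the new one absorbs
        counts: Counter[frozenset[int]] = Counter()
        for v in cells:
            counts.update(self._by_vertex.get(v, ()))
        for m, k in counts.items():
            if k == len(m):  # every vertex of m is in cells
                del self.maximal[m]
                for v in m:
                    self._by_vertex[v].discard(m)
        self.maximal[cells] = t
        for v in cells:
            self._by_vertex.setdefault(v, set()).add(cells)
        self.log.append((t, cells))
        return True


def insert_coactivity(complex_: CoactivityComplex, cells, t: float) -> CoactivityComplex:
    """Functional wrapper around :meth:`CoactivityComplex.insert`."""
    complex_.insert(cells, t)
    return complex_


def build_complex(events: list[CoactivityEvent]) -> CoactivityComplex:
    cx = CoactivityComplex()
    for ev in events:
        cx.insert(ev.cells, ev.t_start)
    return cx


def order_histogram(complex_: CoactivityComplex, t: float | None = None) -> Counter:
    """Histogram of maximal-simplex orders at time ``t`` (end of session
    if omitted), replaying the insertion log with its eliminations."""
    if t is None:
        return Counter(len(s) for s in complex_.maximal)
    replay = CoactivityComplex()
    for ti, cells in complex_.log:
        if ti > t:
            break
        replay.insert(cells, ti)
    return Counter(len(s) for s in replay.maximal)


def betti_numbers(complex_: CoactivityComplex | list, full: bool = False) -> tuple[int, int]:
    """Betti numbers (b0, b1) of the complex's 2-skeleton over Z2."""
    if isinstance(complex_, CoactivityComplex):
        if not complex_.log:
            raise ValueError("complex is empty")
        # the complex includes every face ever inserted, not only the
        # surviving antichain
        sims = [cells for _, cells in complex_.log]
    else:
        sims = list(complex_)
    return betti_from_maximal(sims, full=full)


def barcodes(complex_: CoactivityComplex) -> Barcode:
    """H0/H1 persistence of the detection-time filtration."""
    return persistence_from_log(complex_.log)


class SimplicialSchema(BaseEstimator):
    """Learner for the coactivity simplicial schema.

    Attributes (after :meth:`fit`)
    ------------------------------
    complex_ : CoactivityComplex
    barcode_ : Barcode
    t_min_ : topological learning time (s)
    t_n_ : saturation time of structural changes (s)
    max_order_ : largest maximal-simplex order observed
    betti_ : (b0, b1) at session end
    n_surviving_loops_ : surviving H1 bars
    """

    def __init__(self, window: float | None = None, tail_tolerance: float = 0.01):
        self.window = window
        self.tail_tolerance = tail_tolerance

    def fit(self, trains: SpikeTrains, y=None):
        window = self.window or coactivity_window(trains.theta_freq)
        events = detect_coactivity(trains, window)
        self.complex_ = build_complex(events)
        self.barcode_ = barcodes(self.complex_)
        self.t_min_ = topological_learning_time(self.barcode_)
        log_times = np.array([t for t, _ in self.complex_.log])
        self.t_n_ = saturation_time(log_times, np.arange(1, len(log_times) + 1),
                                    self.tail_tolerance)
        self.max_order_ = max((len(c) for _, c in self.complex_.log), default=0)
        self.betti_ = self.barcode_.betti_at(trains.duration)
        self.n_surviving_loops_ = self.barcode_.n_surviving(1)
        return self

    def order_histogram_at(self, t: float | None = None) -> Counter:
        return order_histogram(self.complex_, t)

    def report(self) -> dict:
        return {
            "t_min_s": self.t_min_,
            "t_n_s": self.t_n_,
            "max_order": self.max_order_,
            "betti": list(self.betti_),
            "n_surviving_loops": self.n_surviving_loops_,
            "n_maximal": self.complex_.n_maximal,
        }


def write_maximal_simplexes(complex_: CoactivityComplex, path) -> None:
    with open(path, "w") as fh:
        for cells, t in sorted(complex_.maximal.items(), key=lambda kv: (kv[1], sorted(kv[0]))):
            fh.write(f"{t:.4f}\t" + " ".join(str(c) for c in sorted(cells)) + "\n")


def write_barcode(barcode: Barcode, path) -> None:
    pd.DataFrame(
        {
            "dim": [b.dim for b in barcode.bars],
            "birth": [b.birth for b in barcode.bars],
            "death": [b.death for b in barcode.bars],
            "survives": [b.survives for b in barcode.bars],
        }
    ).to_csv(path, index=False)
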