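"""The binary-coactivity graph schema and its integrals.

The graph schema G records, for every cell pair, whether the pair has
cofired before time t (C_ij = 1) — a connection is learned the moment
the first coactivity is observed, so the edge set grows monotonically.
Its information load is the binary entropy of the connected-pair
fraction p_c.  Schema *integrals* are large-scale graph properties
that can stabilize before the full edge set is learned: the time to
path-connect the most distant vertex pairs (T_min), the existence of
an Eulerian path, and the maximal-clique count.  T_N is the time at
which the link count saturates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .activity import CoactivityEvent, coactivity_window, detect_coactivity
from .place_cells import SpikeTrains

__all__ = [
    "CoactivityGraph",
    "build_graph",
    "graph_entropy",
    "distant_pair_connection_time",
    "eulerian_path_exists",
    "count_maximal_cliques",
    "saturation_time",
    "GraphSchema",
]


@dataclass
class CoactivityGraph:
    """Undirected coactivity graph; each edge stamped with its first
    detection time (seconds)."""

    n_vertices: int
    edge_times: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edge_times)

    def edges_before(self, t: float) -> list[tuple[int, int]]:
        return [e for e, te in self.edge_times.items() if te <= t]

    def to_networkx(self, t: float | None = None) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        for (i, j), te in self.edge_times.items():
            if t is None or te <= t:
                g.add_edge(i, j, time=te)
        return g

    def link_timeline(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted edge first-detection times and cumulative link counts."""
        times = np.sort(np.fromiter(self.edge_times.values(), float))
        return times, np.arange(1, len(times) + 1)


def build_graph(events: list[CoactivityEvent], n_vertices: int) -> CoactivityGraph:
    """Accumulate all unordered pairs of each coactivity event, keeping
    the earliest window start time per edge."""
    g = CoactivityGraph(n_vertices=n_vertices)
    for ev in events:
        cells = sorted(ev.cells)
        for a in range(len(cells)):
            for b in range(a + 1, len(cells)):
                e = (cells[a], cells[b])
                if e not in g.edge_times:
                    g.edge_times[e] = ev.t_start
    return g


def graph_entropy(n_edges: int, n_vertices: int) -> float:
    """Binary entropy (bits) of the connected-pair fraction
    p_c = edges / (n(n-1)/2); 0*log(0) is taken as 0."""
    if n_vertices < 2:
        raise ValueError("need at least two vertices")
    p = n_edges / (n_vertices * (n_vertices - 1) / 2)
    if p <= 0 or p >= 1:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def distant_pair_connection_time(graph: CoactivityGraph) -> tuple[float, float]:
    """Time to path-connect all most-distant vertex pairs.

    Most-distant pairs are the vertex pairs at graph distance equal to
    the diameter of the final graph (restricted to its largest
    connected component, with a warning, if disconnected).  Returns
    ``(t_min, fraction)`` where ``fraction`` is the share of final
    edges already present at ``t_min``.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    g = graph.to_networkx()
    g.remove_nodes_from([v for v in g if g.degree(v) == 0])
    if not nx.is_connected(g):
        warnings.warn("final graph is disconnected; using the largest component")
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp).copy()
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    diam = max(max(d.values()) for d in lengths.values())
    pairs = {
        (min(u, v), max(u, v))
        for u, d in lengths.items()
        for v, dist in d.items()
        if dist == diam
    }
    edges = sorted(graph.edge_times.items(), key=lambda kv: kv[1])
    uf = _UnionFind(graph.n_vertices)
    pending = set(pairs)
    for k, ((i, j), te) in enumerate(edges):
        uf.union(i, j)
        pending = {(u, v) for (u, v) in pending if uf.find(u) != uf.find(v)}
        if not pending:
            return float(te), (k + 1) / len(edges)
    raise RuntimeError("diameter pairs not connected by the final graph")  # pragma: no cover


def eulerian_path_exists(graph: CoactivityGraph | nx.Graph, t: float | None = None) -> bool:
    """True iff all edges lie in one connected component and at most two
    vertices have odd degree."""
    g = graph.to_networkx(t) if isinstance(graph, CoactivityGraph) else graph
    g = g.copy()
    g.remove_nodes_from([v for v in list(g) if g.degree(v) == 0])
    if g.number_of_edges() == 0:
        return False
    if not nx.is_connected(g):
        return False
    odd = sum(1 for _, d in g.degree() if d % 2 == 1)
    return odd in (0, 2)


def count_maximal_cliques(graph: CoactivityGraph | nx.Graph, t: float | None = None) -> int:
    """Number of maximal cliques of size >= 2 (Bron–Kerbosch)."""
    g = graph.to_networkx(t) if isinstance(graph, CoactivityGraph) else graph
    return sum(1 for c in nx.find_cliques(g) if len(c) >= 2)


def saturation_time(times: np.ndarray, counts: np.ndarray, tail_tolerance: float = 0.01) -> float:
    """Earliest time after which the (non-decreasing) count grows by
    less than ``tail_tolerance`` of its final value."""
    times = np.asarray(times, float)
    counts = np.asarray(counts, float)
    if len(counts) == 0 or counts[-1] <= 0:
        warnings.warn("flat-zero timeline; saturation time undefined, returning 0")
        return 0.0
    if np.any(np.diff(counts) < 0):
        raise ValueError("timeline must be non-decreasing")
    final = counts[-1]
    remaining = final - counts
    idx = np.flatnonzero(remaining < tail_tolerance * final)
    return float(times[idx[0]])


class GraphSchema(BaseEstimator):
    """Learner for the coactivity-graph schema.

    Parameters
    ----------
    window :
        Coactivity window (s); ``None`` derives two theta periods from
        the spike trains.
    tail_tolerance :
        Plateau criterion for the link-saturation time T_N.

    Attributes (after :meth:`fit`)
    ------------------------------
    graph_ : CoactivityGraph
    n_cells_ : int
    link_times_, link_counts_ : link-growth timeline
    t_n_ : link saturation time (s)
    t_min_ : distant-pair connection time (s)
    frac_links_at_t_min_ : fraction of final links present at t_min_
    entropy_ : asymptotic graph entropy H_G (bits)
    """

    def __init__(self, window: float | None = None, tail_tolerance: float = 0.01):
        self.window = window
        self.tail_tolerance = tail_tolerance

    def fit(self, trains: SpikeTrains, y=None):
        window = self.window or coactivity_window(trains.theta_freq)
        events = detect_coactivity(trains, window)
        self.graph_ = build_graph(events, n_vertices=trains.n_cells)
        self.n_cells_ = trains.n_cells
        self.link_times_, self.link_counts_ = self.graph_.link_timeline()
        self.t_n_ = saturation_time(self.link_times_, self.link_counts_, self.tail_tolerance)
        self.t_min_, self.frac_links_at_t_min_ = distant_pair_connection_time(self.graph_)
        self.entropy_ = graph_entropy(self.graph_.n_edges, trains.n_cells)
        return self

    def entropy_timeline(self, times: np.ndarray) -> np.ndarray:
        """H_G evaluated at the given probe times."""
        counts = np.searchsorted(self.link_times_, times, side="right")
        return np.array([graph_entropy(int(c), self.n_cells_) for c in counts])

    def report(self) -> dict:
        return {
            "n_edges": self.graph_.n_edges,
            "t_n_s": self.t_n_,
            "t_min_s": self.t_min_,
            "frac_links_at_t_min": self.frac_links_at_t_min_,
            "entropy_bits": self.entropy_,
        }


def write_edge_list(graph: CoactivityGraph, path) -> None:
    rows = sorted(graph.edge_times.items(), key=lambda kv: (kv[1], kv[0]))
    pd.DataFrame(
        {"i": [e[0][0] for e in rows], "j": [e[0][1] for e in rows], "t_first": [e[1] for e in rows]}
    ).to_csv(path, index=False)
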