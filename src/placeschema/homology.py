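"""Z2 homology and persistence for coactivity complexes.

Computes Betti numbers b0/b1 and persistence barcodes of a filtered
simplicial complex given as a time-ordered stream of maximal simplexes
(the insertion log of a coactivity complex).  Only dimensions 0 and 1
are computed, on the 2-skeleton: H0 by union-find with the elder rule,
H1 by standard column reduction of the triangle boundary matrix over
Z2, with columns stored as Python integers (bitmasks over edge
indices) so that the XOR of two columns is a single big-int operation.

Triangle economy
----------------
A maximal simplex on k vertices implies C(k, 3) triangles, but its
contribution to the image of the boundary operator — hence to b1 —
is spanned by the C(k-1, 2) "cone" triangles through one fixed vertex
(any cycle inside a clique is a Z2-sum of triangles through a common
apex).  Per inserted simplex we therefore add only the cone through
its smallest vertex.  At every filtration stage the span of the added
triangle columns equals the span of the full 2-skeleton's columns, so
the H0/H1 persistence diagram is exactly that of the full 2-skeleton;
the test suite checks this against a brute-force boundary-matrix
oracle on the full face lattice.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Barcode", "persistence_from_log", "betti_from_maximal", "topological_learning_time"]

_INF = math.inf


@dataclass(frozen=True)
class Bar:
    dim: int
    birth: float
    death: float  # math.inf if the class survives to session end

    @property
    def survives(self) -> bool:
        return math.isinf(self.death)


@dataclass
class Barcode:
    """Persistence bars in dimensions 0 and 1 (zero-length bars dropped)."""

    bars: list[Bar] = field(default_factory=list)

    def in_dim(self, dim: int) -> list[Bar]:
        return [b for b in self.bars if b.dim == dim]

    def n_surviving(self, dim: int) -> int:
        return sum(1 for b in self.in_dim(dim) if b.survives)

    def betti_at(self, t: float) -> tuple[int, int]:
        b = [0, 0]
        for bar in self.bars:
            if bar.birth <= t < bar.death:
                b[bar.dim] += 1
        return b[0], b[1]

    def finite_deaths(self) -> list[float]:
        return [b.death for b in self.bars if not b.survives]


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}
        self.birth: dict[int, tuple] = {}  # root -> (time, order) of oldest member

    def add(self, v: int, stamp: tuple) -> None:
        if v not in self.parent:
            self.parent[v] = v
            self.birth[v] = stamp

    def find(self, v: int) -> int:
        root = v
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[v] != root:
            self.parent[v], v = root, self.parent[v]
        return root

    def union(self, a: int, b: int) -> tuple | None:
        """Merge; return the birth stamp of the *younger* component if a
        merge happened, else None."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return None
        if self.birth[ra] <= self.birth[rb]:
            old, young = ra, rb
        else:
            old, young = rb, ra
        stamp = self.birth[young]
        self.parent[young] = old
        return stamp


def _filtration_from_log(log):
    """First-appearance times of vertices, edges and cone triangles.

    ``log`` is a time-ordered iterable of ``(t, cells)`` with ``cells``
    an iterable of vertex ids.
    """
    verts: dict[int, float] = {}
    edges: dict[tuple[int, int], float] = {}
    tris: dict[tuple[int, int, int], float] = {}
    for t, cells in log:
        cs = sorted(set(cells))
        for v in cs:
            verts.setdefault(v, t)
        for a, b in itertools.combinations(cs, 2):
            edges.setdefault((a, b), t)
        if len(cs) >= 3:
            apex = cs[0]
            for a, b in itertools.combinations(cs[1:], 2):
                tris.setdefault((apex, a, b), t)
    return verts, edges, tris


def persistence_from_log(log, t_end: float | None = None) -> Barcode:
    """Persistence barcode (H0 and H1) of a filtered coactivity complex.

    Each face appears at the earliest time any logged simplex contains
    it; ties are broken lexicographically by vertex ids.  Classes alive
    at the end of the log survive (death = inf).
    """
    verts, edges, tris = _filtration_from_log(log)
    bars: list[Bar] = []

    # --- H0: union-find with the elder rule ------------------------------
    edge_order = sorted(edges, key=lambda e: (edges[e], e))
    edge_index = {e: k for k, e in enumerate(edge_order)}
    uf = _UnionFind()
    vert_order = sorted(verts, key=lambda v: (verts[v], v))
    for k, v in enumerate(vert_order):
        uf.add(v, (verts[v], k))
    merging: set[int] = set()  # indices of negative (component-merging) edges
    for k, e in enumerate(edge_order):
        stamp = uf.union(e[0], e[1])
        if stamp is not None:
            merging.add(k)
            if edges[e] > stamp[0]:
                bars.append(Bar(0, stamp[0], edges[e]))
    roots = {uf.find(v) for v in verts}
    for r in roots:
        bars.append(Bar(0, uf.birth[r][0], _INF))

    # --- H1: reduce the triangle boundary matrix over Z2 ------------------
    # columns are ints; bit k is edge edge_order[k]; low = highest set bit
    reduced: dict[int, int] = {}  # pivot edge index -> reduced column
    pair_death: dict[int, float] = {}  # pivot edge index -> triangle time
    for tri in sorted(tris, key=lambda s: (tris[s], s)):
        a, b, c = tri
        col = (
            (1 << edge_index[(a, b)])
            | (1 << edge_index[(a, c)])
            | (1 << edge_index[(b, c)])
        )
        while col:
            low = col.bit_length() - 1
            if low in reduced:
                col ^= reduced[low]
            else:
                reduced[low] = col
                pair_death[low] = tris[tri]
                break
    for k, e in enumerate(edge_order):
        if k in merging:
            continue  # negative edge: belongs to an H0 pair
        birth = edges[e]
        death = pair_death.get(k, _INF)
        if death > birth:
            bars.append(Bar(1, birth, death))
        # zero-length loops (killed within the same window) are dropped
    return Barcode(bars=sorted(bars, key=lambda b: (b.dim, b.birth, b.death)))


def topological_learning_time(barcode: Barcode) -> float:
    """Latest death among non-surviving bars (H0 and H1): the first time
    after which the Betti numbers hold their session-end values."""
    deaths = barcode.finite_deaths()
    return max(deaths) if deaths else 0.0


def betti_from_maximal(maximal_simplexes, full: bool = False) -> tuple[int, int]:
    """Betti numbers (b0, b1) of the complex spanned by the given
    maximal simplexes, over Z2, on the 2-skeleton.

    With ``full=True`` every implied triangle is enumerated; the default
    uses the homology-equivalent cone triangles (see module docstring).
    """
    sims = [sorted(set(s)) for s in maximal_simplexes]
    if not sims:
        return 0, 0
    verts: set[int] = set()
    edges: set[tuple[int, int]] = set()
    tris: set[tuple[int, int, int]] = set()
    for cs in sims:
        verts.update(cs)
        edges.update(itertools.combinations(cs, 2))
        if len(cs) >= 3:
            if full:
                tris.update(itertools.combinations(cs, 3))
            else:
                apex = cs[0]
                tris.update((apex, a, b) for a, b in itertools.combinations(cs[1:], 2))

    uf = _UnionFind()
    for k, v in enumerate(sorted(verts)):
        uf.add(v, (0.0, k))
    n_merges = 0
    edge_order = sorted(edges)
    edge_index = {e: k for k, e in enumerate(edge_order)}
    for e in edge_order:
        if uf.union(e[0], e[1]) is not None:
            n_merges += 1
    b0 = len(verts) - n_merges

    reduced: dict[int, int] = {}
    rank2 = 0
    for a, b, c in sorted(tris):
        col = (
            (1 << edge_index[(a, b)])
            | (1 << edge_index[(a, c)])
            | (1 << edge_index[(b, c)])
        )
        while col:
            low = col.bit_length() - 1
            if low in reduced:
                col ^= reduced[low]
            else:
                reduced[low] = col
                rank2 += 1
                break
    b1 = len(edges) - (len(verts) - b0) - rank2
    return b0, b1
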