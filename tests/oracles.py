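"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: dense GF(2) linear algebra on
the full face lattice, exhaustive subset enumeration, explicit path
construction, dense time-grid sweeps.  None of it shares code with the
package implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def gf2_rank(matrix: np.ndarray) -> int:
    """Rank of a 0/1 matrix over GF(2) by Gaussian elimination."""
    m = (np.asarray(matrix, dtype=np.uint8) % 2).copy()
    rank = 0
    rows, cols = m.shape
    for c in range(cols):
        pivot = None
        for r in range(rank, rows):
            if m[r, c]:
                pivot = r
                break
        if pivot is None:
            continue
        m[[rank, pivot]] = m[[pivot, rank]]
        for r in range(rows):
            if r != rank and m[r, c]:
                m[r] ^= m[rank]
        rank += 1
    return rank


def betti_full_lattice(maximal_simplexes) -> tuple[int, int]:
    """Betti numbers b0, b1 of the full simplicial complex spanned by
    the given maximal simplexes (every face enumerated), over GF(2)."""
    faces: set[frozenset] = set()
    for s in maximal_simplexes:
        s = frozenset(s)
        for k in range(1, len(s) + 1):
            for f in itertools.combinations(sorted(s), k):
                faces.add(frozenset(f))
    verts = sorted(f for f in faces if len(f) == 1)
    edges = sorted((tuple(sorted(f)) for f in faces if len(f) == 2))
    tris = sorted((tuple(sorted(f)) for f in faces if len(f) == 3))
    vi = {tuple(v)[0]: k for k, v in enumerate(verts)}
    ei = {e: k for k, e in enumerate(edges)}
    d1 = np.zeros((len(verts), len(edges)), dtype=np.uint8)
    for e, k in ei.items():
        d1[vi[e[0]], k] = 1
        d1[vi[e[1]], k] = 1
    d2 = np.zeros((len(edges), len(tris)), dtype=np.uint8)
    for k, (a, b, c) in enumerate(tris):
        d2[ei[(a, b)], k] = 1
        d2[ei[(a, c)], k] = 1
        d2[ei[(b, c)], k] = 1
    r1 = gf2_rank(d1) if edges else 0
    r2 = gf2_rank(d2) if tris else 0
    b0 = len(verts) - r1
    b1 = len(edges) - r1 - r2
    return b0, b1


def hierholzer_eulerian_path(edges: list[tuple[int, int]]) -> bool:
    """Explicitly construct an Eulerian path over the multigraph given
    by ``edges``; returns True iff one exists."""
    if not edges:
        return False
    adj: dict[int, list[int]] = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append(k)
        adj.setdefault(v, []).append(k)
    odd = [v for v, inc in adj.items() if len(inc) % 2 == 1]
    start = odd[0] if odd else edges[0][0]
    used = [False] * len(edges)
    stack = [start]
    path = []
    inc_pos = {v: 0 for v in adj}
    while stack:
        v = stack[-1]
        advanced = False
        while inc_pos[v] < len(adj[v]):
            k = adj[v][inc_pos[v]]
            inc_pos[v] += 1
            if not used[k]:
                used[k] = True
                u, w = edges[k]
                stack.append(w if u == v else u)
                advanced = True
                break
        if not advanced:
            path.append(stack.pop())
    if not (all(used) and len(path) == len(edges) + 1):
        return False
    # validate that the produced vertex sequence is an actual trail
    # consuming each edge exactly once
    remaining = list(range(len(edges)))
    for u, v in zip(path[:-1], path[1:]):
        hit = None
        for k in remaining:
            if {edges[k][0], edges[k][1]} == {u, v}:
                hit = k
                break
        if hit is None:
            return False
        remaining.remove(hit)
    return not remaining


def maximal_cliques_bruteforce(n: int, edges: set[tuple[int, int]]) -> int:
    """Count maximal cliques of size >= 2 by enumerating all vertex
    subsets (n <= ~15)."""
    adj = {v: set() for v in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def is_clique(sub) -> bool:
        return all(v in adj[u] for u, v in itertools.combinations(sub, 2))

    count = 0
    verts = list(range(n))
    for size in range(2, n + 1):
        for sub in itertools.combinations(verts, size):
            if not is_clique(sub):
                continue
            extendable = any(
                all(w in adj[u] for u in sub) for w in verts if w not in sub
            )
            if not extendable:
                count += 1
    return count


def distant_pair_time_prefix_scan(n: int, edge_times: dict[tuple[int, int], float]) -> float:
    """Earliest time every final-graph diameter pair is path-connected,
    by re-testing connectivity at every prefix of the edge sequence."""
    import networkx as nx

    g = nx.Graph(list(edge_times))
    if not nx.is_connected(g):
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp)
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    diam = max(max(d.values()) for d in lengths.values())
    pairs = {
        (min(u, v), max(u, v))
        for u, d in lengths.items()
        for v, dist in d.items()
        if dist == diam
    }
    for t in sorted(set(edge_times.values())):
        h = nx.Graph([e for e, te in edge_times.items() if te <= t])
        if all(u in h and v in h and nx.has_path(h, u, v) for u, v in pairs):
            return t
    raise AssertionError("pairs never connected")


def rcc5_finite_model_composition() -> dict[tuple[str, str], frozenset[str]]:
    """RCC5 composition by enumerating all region triples over a
    4-element universe."""

    def rel(x: frozenset, y: frozenset) -> str:
        if x == y:
            return "EQ"
        if not (x & y):
            return "DR"
        if x < y:
            return "PP"
        if y < x:
            return "PPi"
        return "PO"

    universe = range(4)
    regions = [
        frozenset(s)
        for k in range(1, 5)
        for s in itertools.combinations(universe, k)
    ]
    table: dict[tuple[str, str], set[str]] = {}
    for x in regions:
        for y in regions:
            rxy = rel(x, y)
            for z in regions:
                table.setdefault((rxy, rel(y, z)), set()).add(rel(x, z))
    return {k: frozenset(v) for k, v in table.items()}


def count_inconsistencies_naive(labels, n: int, composition) -> int:
    """Ordered-triple composition violations by a plain triple loop.
    ``labels(i, j)`` returns the label of the ordered pair."""
    bad = 0
    for x in range(n):
        for y in range(n):
            if y == x:
                continue
            for z in range(n):
                if z == x or z == y:
                    continue
                if labels(x, z) not in composition[(labels(x, y), labels(y, z))]:
                    bad += 1
    return bad
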