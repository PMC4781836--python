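"""The spatial map: reconstructed place fields, overlap structure and
schema-vs-map information measures.

Place fields are reconstructed as convex hulls of each cell's spike
locations after discarding outliers (spikes farther than 3 median
absolute deviations from the spike centroid).  Crisp convex regions
deliberately overstate high-order overlaps relative to the coactivity
schema — a property of the representation, not a bug.

The overlap structure of the reconstructed map is computed by
rasterizing the regions on a grid and collecting the maximal region
combinations with common points; these are exactly the maximal
simplexes of the Cech nerve of the place-field cover.  Schema and map
are compared through the entropies of their relationship streams and
the mutual information between them.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Polygon

from .place_cells import SpikeTrains
from .simplicial_schema import CoactivityComplex

__all__ = [
    "PlaceFieldMap",
    "construct_place_fields",
    "overlap_orders",
    "nerve",
    "entropy_bits",
    "mutual_information",
    "schema_map_information",
    "EntropyMITimeline",
    "polygon_rcc5",
]


@dataclass
class PlaceFieldMap:
    """Reconstructed place fields: convex polygons per cell id."""

    regions: dict[int, Polygon] = field(default_factory=dict)
    degenerate: set[int] = field(default_factory=set)
    grid_step: float = 0.01

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.regions)


def construct_place_fields(
    trains: SpikeTrains, min_spikes: int = 10, mad_factor: float = 3.0
) -> PlaceFieldMap:
    """Convex hulls of per-cell spike clusters.

    Cells with fewer than ``min_spikes`` spikes are omitted; spikes
    farther than ``mad_factor`` median absolute deviations from the
    spike centroid are discarded before hulling.  Collinear spike sets
    are flagged degenerate and excluded from polygon operations.
    """
    if min_spikes < 3:
        raise ValueError("min_spikes must be at least 3")
    fmap = PlaceFieldMap()
    for cid, xy in trains.positions.items():
        if len(xy) < min_spikes:
            continue
        centroid = np.median(xy, axis=0)
        d = np.linalg.norm(xy - centroid, axis=1)
        mad = np.median(np.abs(d - np.median(d)))
        if mad > 0:
            keep = xy[np.abs(d - np.median(d)) <= mad_factor * mad]
        else:
            keep = xy[d <= 1e-12] if np.all(d <= 1e-12) else xy
        if len(keep) < 3:
            keep = xy
        hull = MultiPoint([tuple(p) for p in keep]).convex_hull
        if not isinstance(hull, Polygon) or hull.area <= 0:
            fmap.degenerate.add(cid)
            continue
        fmap.regions[cid] = hull
    return fmap


def _maximal_combinations(cover_sets) -> list[frozenset[int]]:
    """Deduplicate covering sets and keep the inclusion-maximal ones."""
    distinct = sorted(set(cover_sets), key=len, reverse=True)
    maximal: list[frozenset[int]] = []
    by_vertex: dict[int, list[frozenset[int]]] = {}
    for s in distinct:
        probe = min((by_vertex.get(v, []) for v in s), key=len, default=[])
        if any(s <= m for m in probe):
            continue
        maximal.append(s)
        for v in s:
            by_vertex.setdefault(v, []).append(s)
    return maximal


def overlap_orders(
    fmap: PlaceFieldMap, grid_step: float = 0.01
) -> tuple[Counter, list[frozenset[int]]]:
    """Overlap structure of the reconstructed map on a raster grid.

    Returns ``(orders, combos)`` where ``combos`` are the maximal
    region combinations sharing at least one grid point and ``orders``
    counts them by size.
    """
    import shapely

    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if not fmap.regions:
        return Counter(), []
    bounds = np.array([fmap.regions[c].bounds for c in fmap.cell_ids])
    xmin, ymin = bounds[:, :2].min(axis=0)
    xmax, ymax = bounds[:, 2:].max(axis=0)
    xs = np.arange(xmin, xmax + grid_step, grid_step)
    ys = np.arange(ymin, ymax + grid_step, grid_step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    px, py = gx.ravel(), gy.ravel()
    covers = np.zeros((len(px), 0), dtype=bool)
    ids = fmap.cell_ids
    cols = []
    for cid in ids:
        cols.append(shapely.contains_xy(fmap.regions[cid], px, py))
    covers = np.column_stack(cols) if cols else covers
    occupied = covers.any(axis=1)
    combos = {
        frozenset(ids[k] for k in np.flatnonzero(row))
        for row in covers[occupied]
    }
    maximal = _maximal_combinations(combos)
    return Counter(len(c) for c in maximal), maximal


def nerve(fmap: PlaceFieldMap, grid_step: float = 0.01) -> CoactivityComplex:
    """Cech nerve of the place-field cover: maximal simplexes are the
    maximal region combinations with non-empty common intersection."""
    _, combos = overlap_orders(fmap, grid_step)
    cx = CoactivityComplex()
    for combo in sorted(combos, key=lambda c: (len(c), sorted(c))):
        cx.insert(combo, 0.0)
    return cx


# ---------------------------------------------------------------------------
# entropy and mutual information of relationship streams
# ---------------------------------------------------------------------------

def entropy_bits(labels) -> float:
    """Entropy (bits) of the empirical distribution of a label stream."""
    counts = Counter(labels)
    n = sum(counts.values())
    if n == 0:
        return 0.0
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * np.log2(p)
    return float(h)


def mutual_information(xs, ys) -> float:
    """Sample mutual information (bits) of two aligned label streams."""
    xs, ys = list(xs), list(ys)
    if len(xs) != len(ys):
        raise ValueError("streams must be aligned")
    n = len(xs)
    if n == 0:
        return 0.0
    joint = Counter(zip(xs, ys))
    px = Counter(xs)
    py = Counter(ys)
    mi = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        mi += pxy * np.log2(pxy * n * n / (px[x] * py[y]))
    return float(max(mi, 0.0))


@dataclass
class EntropyMITimeline:
    times: np.ndarray
    h_schema: np.ndarray
    h_map: np.ndarray
    mi: np.ndarray


def schema_map_information(
    times, schema_labels, map_labels, n_probes: int = 50
) -> EntropyMITimeline:
    """Cumulative entropies of the schema and map relationship streams
    and the mutual information between them, along the session.

    ``times`` are the window times of the aligned label streams; the
    quantities are evaluated on ``n_probes`` evenly spaced prefixes.
    """
    times = np.asarray(times, float)
    schema_labels = list(schema_labels)
    map_labels = list(map_labels)
    if not (len(times) == len(schema_labels) == len(map_labels)):
        raise ValueError("streams must be aligned with times")
    if len(times) == 0:
        z = np.array([])
        return EntropyMITimeline(times=z, h_schema=z, h_map=z, mi=z)
    probe_idx = np.unique(np.linspace(1, len(times), n_probes).astype(int))
    out_t, out_hs, out_hm, out_mi = [], [], [], []
    for k in probe_idx:
        out_t.append(times[k - 1])
        out_hs.append(entropy_bits(schema_labels[:k]))
        out_hm.append(entropy_bits(map_labels[:k]))
        out_mi.append(mutual_information(schema_labels[:k], map_labels[:k]))
    return EntropyMITimeline(
        times=np.array(out_t), h_schema=np.array(out_hs),
        h_map=np.array(out_hm), mi=np.array(out_mi),
    )


def polygon_rcc5(p: Polygon, q: Polygon, tol: float = 0.05) -> str:
    """RCC5 relation between two polygons by area thresholds.

    ``tol`` is the relative-area tolerance: intersections smaller than
    ``tol * min(area)`` count as empty, and containment/equality hold
    up to ``tol`` of the relevant region's area.
    """
    ap, aq = p.area, q.area
    inter = p.intersection(q).area
    if inter <= tol * min(ap, aq):
        return "DR"
    in_p = inter / ap
    in_q = inter / aq
    if in_p >= 1 - tol and in_q >= 1 - tol:
        return "EQ"
    if in_p >= 1 - tol:
        return "PP"
    if in_q >= 1 - tol:
        return "PPi"
    return "PO"
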