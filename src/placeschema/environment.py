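"""Navigable environments and simulated exploratory trajectories.

An :class:`Environment` is a planar navigable region — an outer boundary
polygon minus zero or more hole polygons.  Three standard geometries are
provided: a square arena with a central hole (the default open-field
setup), a U-shaped corridor track with two dead ends, and a W-shaped
track with three dead ends joined at a single junction.

Trajectories emulate rat exploration: in open arenas a correlated random
walk (Ornstein–Uhlenbeck heading, truncated-normal step speeds,
reflection at walls); on tracks, waypoint-following along the corridor
skeleton with uniform random turn choices at the junction.  All
randomness is driven by a single integer seed, and runs are
bit-reproducible.

Units are SI throughout: meters, seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.prepared import prep

__all__ = [
    "Environment",
    "Trajectory",
    "GeometryError",
    "build_environment",
    "simulate_trajectory",
    "read_trajectory",
    "write_trajectory",
    "occupancy_histogram",
]

#: default corridor width for U/W tracks, meters
TRACK_WIDTH = 0.10


class GeometryError(ValueError):
    """Raised when an environment specification is geometrically invalid."""


@dataclass(frozen=True)
class Environment:
    """A navigable planar region: outer boundary minus holes.

    Parameters
    ----------
    kind :
        One of ``"arena-with-hole"``, ``"U-track"``, ``"W-track"``,
        ``"custom"``.
    outer :
        Outer boundary polygon (meters).
    holes :
        Hole polygons, each strictly inside ``outer`` and pairwise
        disjoint.
    skeleton :
        For track environments, the centerline as a sequence of
        polyline segments (each an ``(n, 2)`` array of vertices);
        ``None`` for arenas.
    """

    kind: str
    outer: Polygon
    holes: tuple[Polygon, ...] = ()
    skeleton: tuple[np.ndarray, ...] | None = None

    def __post_init__(self) -> None:
        if not self.outer.is_valid or self.outer.area <= 0:
            raise GeometryError("outer boundary must be a valid polygon of positive area")
        for h in self.holes:
            if not self.outer.contains(h):
                raise GeometryError("hole is not strictly inside the outer boundary")
        for i, a in enumerate(self.holes):
            for b in self.holes[i + 1 :]:
                if a.intersects(b) and not a.touches(b):
                    raise GeometryError("holes must be pairwise disjoint")
        if self.navigable.area <= 0:
            raise GeometryError("navigable area must be positive")

    @property
    def navigable(self) -> Polygon:
        region = self.outer
        for h in self.holes:
            region = region.difference(h)
        return region

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.outer.bounds

    def contains(self, x: float, y: float) -> bool:
        return self.navigable.buffer(1e-9).contains(Point(x, y))

    def contains_many(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized point-in-navigable-region test for an (n, 2) array."""
        import shapely

        return shapely.contains_xy(self.navigable.buffer(1e-9), xy[:, 0], xy[:, 1])


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled path ``r(t)`` through the navigable region."""

    t: np.ndarray
    xy: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if len(self.t) != len(self.xy):
            raise ValueError("t and xy must have equal length")
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, self.dt, rtol=0, atol=1e-9):
                raise ValueError("time axis must be uniformly spaced by dt")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    @property
    def speeds(self) -> np.ndarray:
        """Instantaneous speeds between consecutive samples (m/s)."""
        d = np.linalg.norm(np.diff(self.xy, axis=0), axis=1)
        return d / self.dt

    def position_at(self, times: np.ndarray) -> np.ndarray:
        """Positions at arbitrary times by nearest-sample lookup."""
        idx = np.clip(np.round((np.asarray(times) - self.t[0]) / self.dt).astype(int), 0, len(self.t) - 1)
        return self.xy[idx]


def _square(cx: float, cy: float, side: float) -> Polygon:
    h = side / 2.0
    return Polygon([(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)])


def _track_environment(kind: str, segments: Sequence[np.ndarray], width: float) -> Environment:
    lines = [LineString(seg) for seg in segments]
    corridor = lines[0].buffer(width / 2.0)
    for ln in lines[1:]:
        corridor = corridor.union(ln.buffer(width / 2.0))
    corridor = corridor.buffer(0)
    return Environment(kind=kind, outer=corridor, holes=(), skeleton=tuple(np.asarray(s, float) for s in segments))


def u_track_skeleton(arm_length: float = 0.6, base_length: float = 0.6) -> tuple[np.ndarray, ...]:
    """U-shaped centerline: two vertical arms joined by a base corridor."""
    half = base_length / 2.0
    pts = np.array(
        [(-half, arm_length), (-half, 0.0), (half, 0.0), (half, arm_length)], float
    )
    return (pts,)

def w_track_skeleton(arm_length: float = 0.6) -> tuple[np.ndarray, ...]:
    """Three straight arms radiating 120 degrees apart from one junction.

    The track has three dead ends and a single junction at the origin —
    the qualitative layout of a W-track maze.
    """
    j = np.array([0.0, 0.0])
    arms = []
    for ang in (90.0, 210.0, 330.0):
        a = math.radians(ang)
        tip = j + arm_length * np.array([math.cos(a), math.sin(a)])
        arms.append(np.array([j, tip]))
    return tuple(arms)


def build_environment(spec: dict | None = None, **kwargs) -> Environment:
    """Build an environment from a specification mapping.

    Recognized keys: ``kind`` (``arena-with-hole`` | ``U-track`` |
    ``W-track`` | ``custom``), ``side`` (arena side, default 1.0),
    ``hole_side`` (default 0.3; 0 disables the hole), ``arm_length``,
    ``base_length``, ``track_width`` (default 0.1), and for ``custom``
    an explicit ``outer``/``holes`` pair of coordinate lists.
    """
    spec = dict(spec or {})
    spec.update(kwargs)
    kind = spec.get("kind", "arena-with-hole")

    if kind == "arena-with-hole":
        side = float(spec.get("side", 1.0))
        hole_side = float(spec.get("hole_side", 0.3))
        if side <= 0 or hole_side < 0:
            raise ValueError("arena dimensions must be positive")
        outer = _square(side / 2, side / 2, side)
        holes: tuple[Polygon, ...] = ()
        if hole_side > 0:
            holes = (_square(side / 2, side / 2, hole_side),)
        return Environment(kind=kind, outer=outer, holes=holes)

    if kind in ("U-track", "u-track"):
        width = float(spec.get("track_width", TRACK_WIDTH))
        if width <= 0:
            raise ValueError("track width must be positive")
        segs = u_track_skeleton(
            arm_length=float(spec.get("arm_length", 0.6)),
            base_length=float(spec.get("base_length", 0.6)),
        )
        return _track_environment("U-track", segs, width)

    if kind in ("W-track", "w-track"):
        width = float(spec.get("track_width", TRACK_WIDTH))
        if width <= 0:
            raise ValueError("track width must be positive")
        segs = w_track_skeleton(arm_length=float(spec.get("arm_length", 0.6)))
        return _track_environment("W-track", segs, width)

    if kind == "custom":
        outer = Polygon(spec["outer"])
        holes = tuple(Polygon(h) for h in spec.get("holes", ()))
        return Environment(kind=kind, outer=outer, holes=holes)

    raise ValueError(f"unknown environment kind: {kind!r}")


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _simulate_arena(
    env: Environment,
    duration: float,
    mean_speed: float,
    dt: float,
    rng: np.random.Generator,
    heading_persistence: float = 1.0,
    speed_cv: float = 0.3,
) -> Trajectory:
    # Correlated random walk: heading diffuses with decorrelation time
    # ~heading_persistence; speed is redrawn each step from a truncated
    # normal.  Steps leaving the navigable region are rejected and the
    # heading resampled, which acts as a (noisy) reflection at walls.
    n = int(round(duration / dt))
    nav = prep(env.navigable.buffer(-1e-6) if env.navigable.buffer(-1e-6).area > 0 else env.navigable)
    xmin, ymin, xmax, ymax = env.bounds

    # start at a uniformly drawn navigable point
    while True:
        p = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
        if nav.contains(Point(p)):
            break

    sigma_phi = math.sqrt(2.0 / heading_persistence)
    phi = rng.uniform(0, 2 * math.pi)
    xy = np.empty((n + 1, 2))
    xy[0] = p
    for i in range(n):
        phi += sigma_phi * math.sqrt(dt) * rng.standard_normal()
        v = mean_speed * (1.0 + speed_cv * rng.standard_normal())
        v = min(max(v, 0.0), 3.0 * mean_speed)
        ok = False
        for _ in range(50):
            q = (p[0] + v * dt * math.cos(phi), p[1] + v * dt * math.sin(phi))
            if nav.contains(Point(q)):
                ok = True
                break
            # bounce: turn away and retry with a perturbed heading
            phi += math.pi + 0.5 * rng.standard_normal()
        if ok:
            p = np.array(q)
        xy[i + 1] = p
    t = np.arange(n + 1) * dt
    return Trajectory(t=t, xy=xy, dt=dt)


class _SkeletonGraph:
    """Waypoint graph over a track centerline for trajectory simulation."""

    def __init__(self, segments: Sequence[np.ndarray]):
        nodes: list[np.ndarray] = []
        self.edges: list[tuple[int, int, np.ndarray, float]] = []

        def node_id(pt: np.ndarray) -> int:
            for k, q in enumerate(nodes):
                if np.linalg.norm(q - pt) < 1e-9:
                    return k
            nodes.append(pt.copy())
            return len(nodes) - 1

        for seg in segments:
            seg = np.asarray(seg, float)
            for a, b in zip(seg[:-1], seg[1:]):
                ia, ib = node_id(a), node_id(b)
                length = float(np.linalg.norm(b - a))
                self.edges.append((ia, ib, np.vstack([a, b]), length))
        self.nodes = nodes
        self.incident: dict[int, list[int]] = {}
        for ei, (ia, ib, _, _) in enumerate(self.edges):
            self.incident.setdefault(ia, []).append(ei)
            self.incident.setdefault(ib, []).append(ei)

    def point(self, edge: int, s: float) -> np.ndarray:
        ia, ib, geom, length = self.edges[edge]
        u = geom[1] - geom[0]
        return geom[0] + (s / length) * u


def _simulate_track(
    env: Environment,
    duration: float,
    mean_speed: float,
    dt: float,
    rng: np.random.Generator,
    speed_cv: float = 0.3,
) -> Trajectory:
    graph = _SkeletonGraph(env.skeleton)
    n = int(round(duration / dt))
    edge = int(rng.integers(len(graph.edges)))
    ia, ib, _, length = graph.edges[edge]
    s = rng.uniform(0, length)
    direction = 1 if rng.random() < 0.5 else -1
    xy = np.empty((n + 1, 2))
    xy[0] = graph.point(edge, s)
    for i in range(n):
        v = mean_speed * (1.0 + speed_cv * rng.standard_normal())
        v = min(max(v, 0.1 * mean_speed), 3.0 * mean_speed)
        s += direction * v * dt
        ia, ib, _, length = graph.edges[edge]
        while s < 0 or s > length:
            # arrived at a node: pick the next corridor uniformly among
            # the others (reverse at dead ends)
            if s < 0:
                node, overshoot = ia, -s
            else:
                node, overshoot = ib, s - length
            options = [e for e in graph.incident[node] if e != edge]
            nxt = options[int(rng.integers(len(options)))] if options else edge
            edge = nxt
            ia2, ib2, _, length2 = graph.edges[edge]
            if ia2 == node:
                s, direction = overshoot, 1
            else:
                s, direction = length2 - overshoot, -1
            ia, ib, length = ia2, ib2, length2
        xy[i + 1] = graph.point(edge, s)
    t = np.arange(n + 1) * dt
    return Trajectory(t=t, xy=xy, dt=dt)


def simulate_trajectory(
    env: Environment,
    duration: float,
    mean_speed: float = 0.2,
    dt: float = 0.01,
    seed: int | None = None,
) -> Trajectory:
    """Simulate an exploratory trajectory through ``env``.

    Arenas use a correlated random walk with reflection at walls;
    track environments use waypoint navigation along the corridor
    skeleton with uniform random turn choices at junctions.  With a
    fixed ``seed`` the result is bit-reproducible.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if mean_speed <= 0:
        raise ValueError("mean_speed must be positive")
    rng = np.random.default_rng(seed)
    if env.skeleton is not None:
        return _simulate_track(env, duration, mean_speed, dt, rng)
    return _simulate_arena(env, duration, mean_speed, dt, rng)


def occupancy_histogram(env: Environment, traj: Trajectory, bin_size: float = 0.1):
    """Occupancy (sample counts) over square spatial bins.

    Returns ``(counts, navigable_mask)`` where ``navigable_mask`` marks
    bins whose center lies in the navigable region.
    """
    xmin, ymin, xmax, ymax = env.bounds
    nx = max(1, int(math.ceil((xmax - xmin) / bin_size - 1e-9)))
    ny = max(1, int(math.ceil((ymax - ymin) / bin_size - 1e-9)))
    counts, _, _ = np.histogram2d(
        traj.xy[:, 0], traj.xy[:, 1], bins=[nx, ny], range=[[xmin, xmax], [ymin, ymax]]
    )
    cx = xmin + (np.arange(nx) + 0.5) * (xmax - xmin) / nx
    cy = ymin + (np.arange(ny) + 0.5) * (ymax - ymin) / ny
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mask = env.contains_many(pts).reshape(nx, ny)
    return counts, mask


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV with columns ``t,x,y`` (SI units)."""
    pd.DataFrame({"t": traj.t, "x": traj.xy[:, 0], "y": traj.xy[:, 1]}).to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    """Read a ``t,x,y`` CSV written by :func:`write_trajectory`."""
    df = pd.read_csv(path)
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"trajectory CSV is missing column {col!r}")
    t = df["t"].to_numpy(float)
    if len(t) >= 2:
        steps = np.diff(t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("trajectory time axis must be strictly increasing and uniform")
        dt = float(steps[0])
    else:
        dt = 0.0
    return Trajectory(t=t, xy=df[["x", "y"]].to_numpy(float), dt=dt)
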