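"""Place-cell ensembles and theta-modulated Poisson spike generation.

Each place cell fires with a Gaussian spatial tuning curve

    lambda_i(r) = f_i * exp(-|r - r_i|^2 / (2 * width_i^2)),

where ``f_i`` is the peak rate (Hz), ``r_i`` the field center and
``width_i`` the Gaussian width (m).  Ensembles draw peak rates and
place-field *sizes* from gamma distributions (positive support,
unimodal, coefficient of variation 0.3 by default) and centers
uniformly over the navigable region.

"Field size" follows the convention of the experimental literature:
the diameter of the region where the rate exceeds 20% of the peak.
For a Gaussian tuning curve that diameter is ``2*sqrt(2*ln 5)*sigma``,
so a 20 cm field corresponds to ``sigma ~ 5.6 cm``.

Spiking along a trajectory is an inhomogeneous Poisson process with a
multiplicative theta modulation ``m(t) = 1 + depth*cos(2*pi*f_theta*t)``
(mean 1, so expected counts equal the unmodulated model), realized by
thinning on the trajectory's time grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import Environment, Trajectory

__all__ = [
    "FIELD_SIZE_TO_SIGMA",
    "PlaceCell",
    "PlaceCellEnsemble",
    "SpikeTrains",
    "sample_ensemble",
    "rate_at",
    "generate_spikes",
    "track_place_cells",
    "write_spikes",
    "read_spikes",
]

#: field diameter (20%-of-peak contour) per unit Gaussian width
FIELD_SIZE_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(5.0))  # ~3.589


@dataclass(frozen=True)
class PlaceCell:
    """A single place cell: Gaussian firing field."""

    id: int
    center: tuple[float, float]
    peak_rate: float  # f_i, Hz
    width: float  # Gaussian width sigma_i, meters

    def __post_init__(self) -> None:
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be positive")
        if self.width <= 0:
            raise ValueError("width must be positive")

    @property
    def field_size(self) -> float:
        """Field diameter at the 20%-of-peak contour (m)."""
        return self.width * FIELD_SIZE_TO_SIGMA


@dataclass(frozen=True)
class PlaceCellEnsemble:
    cells: tuple[PlaceCell, ...]
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.cells])

    @property
    def peak_rates(self) -> np.ndarray:
        return np.array([c.peak_rate for c in self.cells])

    @property
    def widths(self) -> np.ndarray:
        return np.array([c.width for c in self.cells])


@dataclass(frozen=True)
class SpikeTrains:
    """Per-cell sorted spike times and the positions at which they occurred."""

    times: dict[int, np.ndarray]
    positions: dict[int, np.ndarray]
    duration: float
    theta_freq: float
    n_cells: int

    def __post_init__(self) -> None:
        for cid, t in self.times.items():
            if np.any(np.diff(t) < 0):
                raise ValueError(f"spike times of cell {cid} are not sorted")
            if len(t) and (t[0] < 0 or t[-1] > self.duration + 1e-9):
                raise ValueError(f"spike times of cell {cid} outside [0, duration]")

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.times)

    @property
    def total_spikes(self) -> int:
        return sum(len(t) for t in self.times.values())


def _gamma(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=size)


def sample_ensemble(
    env: Environment,
    n: int = 200,
    f_mean: float = 12.0,
    s_mean: float = 0.2,
    cv: float = 0.3,
    seed: int | None = None,
) -> PlaceCellEnsemble:
    """Sample an ensemble of ``n`` place cells.

    Centers are uniform over the navigable region; peak rates and field
    sizes are gamma-distributed with means ``f_mean`` (Hz) and
    ``s_mean`` (m) and coefficient of variation ``cv``.  The Gaussian
    widths are ``size / FIELD_SIZE_TO_SIGMA``.
    """
    if n < 1:
        raise ValueError("ensemble must contain at least one cell")
    if f_mean <= 0 or s_mean <= 0:
        raise ValueError("means must be positive")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = env.bounds
    centers: list[tuple[float, float]] = []
    while len(centers) < n:
        m = 2 * (n - len(centers)) + 8
        pts = np.column_stack([rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)])
        inside = env.contains_many(pts)
        for p in pts[inside]:
            if len(centers) < n:
                centers.append((float(p[0]), float(p[1])))
    f = _gamma(rng, f_mean, cv, n)
    s = _gamma(rng, s_mean, cv, n)
    cells = tuple(
        PlaceCell(id=i, center=centers[i], peak_rate=float(f[i]), width=float(s[i]) / FIELD_SIZE_TO_SIGMA)
        for i in range(n)
    )
    return PlaceCellEnsemble(cells=cells, seed=seed)


def track_place_cells(
    env: Environment,
    spacing: float = 0.3,
    field_size: float | None = None,
    peak_rate: float = 12.0,
) -> PlaceCellEnsemble:
    """Deterministic place fields tiling a track centerline.

    Cells are laid out along each skeleton segment at ``spacing``
    intervals, shared endpoints (the junction of a W-track) merged.
    Adjacent fields overlap; fields two steps apart do not, so the
    expected overlap degrees are 1 for dead-end cells, 2 for midpoints
    and the number of arms for the junction.
    """
    if env.skeleton is None:
        raise ValueError("track_place_cells requires a track environment")
    if field_size is None:
        field_size = spacing  # adjacent overlap, next-neighbor separation
    pts: list[np.ndarray] = []

    def add(p: np.ndarray) -> None:
        for q in pts:
            if np.linalg.norm(q - p) < 1e-9:
                return
        pts.append(p)

    for seg in env.skeleton:
        seg = np.asarray(seg, float)
        for a, b in zip(seg[:-1], seg[1:]):
            length = float(np.linalg.norm(b - a))
            k = max(1, int(round(length / spacing)))
            for j in range(k + 1):
                add(a + (j / k) * (b - a))
    cells = tuple(
        PlaceCell(id=i, center=(float(p[0]), float(p[1])), peak_rate=peak_rate,
                  width=field_size / FIELD_SIZE_TO_SIGMA)
        for i, p in enumerate(pts)
    )
    return PlaceCellEnsemble(cells=cells)


def rate_at(cell: PlaceCell, position) -> float | np.ndarray:
    """Firing rate lambda_i at ``position`` (a point or an (n, 2) array)."""
    pos = np.asarray(position, float)
    d2 = np.sum((pos - np.asarray(cell.center)) ** 2, axis=-1)
    return cell.peak_rate * np.exp(-d2 / (2.0 * cell.width**2))


def generate_spikes(
    ensemble: PlaceCellEnsemble,
    traj: Trajectory,
    theta_freq: float = 8.0,
    theta_depth: float = 1.0,
    seed: int | None = None,
) -> SpikeTrains:
    """Inhomogeneous-Poisson spike trains along a trajectory.

    Rates are ``lambda_i(r(t)) * (1 + theta_depth*cos(2 pi theta_freq t))``,
    thinned on the trajectory time grid (one Bernoulli draw per grid
    step per cell, exact for piecewise-constant rates at dt much
    smaller than the theta period).
    """
    if len(traj.t) == 0:
        raise ValueError("trajectory is empty")
    if theta_freq <= 0:
        raise ValueError("theta frequency must be positive")
    rng = np.random.default_rng(seed)
    mod = 1.0 + theta_depth * np.cos(2 * np.pi * theta_freq * traj.t)
    times: dict[int, np.ndarray] = {}
    positions: dict[int, np.ndarray] = {}
    for cell in ensemble.cells:
        lam = rate_at(cell, traj.xy) * mod
        p = np.clip(lam * traj.dt, 0.0, 1.0)
        hits = rng.random(len(p)) < p
        idx = np.flatnonzero(hits)
        times[cell.id] = traj.t[idx].copy()
        positions[cell.id] = traj.xy[idx].copy()
    return SpikeTrains(
        times=times,
        positions=positions,
        duration=float(traj.t[-1]),
        theta_freq=theta_freq,
        n_cells=ensemble.n,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spikes(trains: SpikeTrains, path) -> None:
    """Write spikes as CSV with columns ``cell_id,t,x,y``."""
    rows = []
    for cid in trains.cell_ids:
        t = trains.times[cid]
        xy = trains.positions[cid]
        rows.append(pd.DataFrame({"cell_id": cid, "t": t, "x": xy[:, 0], "y": xy[:, 1]}))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["cell_id", "t", "x", "y"])
    df.to_csv(path, index=False)


def read_spikes(path, duration: float | None = None, theta_freq: float = 8.0,
                n_cells: int | None = None) -> SpikeTrains:
    df = pd.read_csv(path)
    for col in ("cell_id", "t"):
        if col not in df.columns:
            raise ValueError(f"spike CSV is missing column {col!r}")
    times: dict[int, np.ndarray] = {}
    positions: dict[int, np.ndarray] = {}
    for cid, grp in df.groupby("cell_id"):
        order = np.argsort(grp["t"].to_numpy())
        times[int(cid)] = grp["t"].to_numpy(float)[order]
        if {"x", "y"} <= set(df.columns):
            positions[int(cid)] = grp[["x", "y"]].to_numpy(float)[order]
        else:
            positions[int(cid)] = np.zeros((len(grp), 2))
    if duration is None:
        duration = float(df["t"].max()) if len(df) else 0.0
    if n_cells is None:
        n_cells = len(times)
    return SpikeTrains(times=times, positions=positions, duration=duration,
                       theta_freq=theta_freq, n_cells=n_cells)


def write_ensemble(ensemble: PlaceCellEnsemble, path) -> None:
    data = [
        {"id": c.id, "x": c.center[0], "y": c.center[1], "f": c.peak_rate, "s": c.field_size}
        for c in ensemble.cells
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_ensemble(path) -> PlaceCellEnsemble:
    with open(path) as fh:
        data = json.load(fh)
    cells = tuple(
        PlaceCell(id=int(d["id"]), center=(d["x"], d["y"]), peak_rate=d["f"],
                  width=d["s"] / FIELD_SIZE_TO_SIGMA)
        for d in data
    )
    return PlaceCellEnsemble(cells=cells)
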