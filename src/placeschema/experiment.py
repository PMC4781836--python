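"""End-to-end experiment orchestration.

A single run simulates an exploratory session (environment, ensemble,
trajectory, spikes) and fits the enabled schema learners; a batch runs
several seeds and aggregates the scalar outcomes (median and
interquartile range).  Defaults reproduce the reference study
conditions: 200 cells, 12 Hz mean peak rate, 20 cm mean field size,
1x1 m arena with a central 0.3 m hole, 25 min session, 8 Hz theta,
250 ms coactivity windows.

The trajectory, ensemble and spiking substreams use independent
sub-seeds derived from the run seed, so each component can be varied
in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .activity import coactivity_window, detect_coactivity
from .environment import Environment, build_environment, simulate_trajectory
from .graph_schema import GraphSchema
from .map_analysis import (
    construct_place_fields,
    mutual_information,
    polygon_rcc5,
    schema_map_information,
)
from .mereo_schema import MereologicalSchema
from .place_cells import PlaceCellEnsemble, generate_spikes, sample_ensemble, track_place_cells
from .rcc5_schema import RCC5Schema
from .simplicial_schema import SimplicialSchema

__all__ = ["ExperimentConfig", "run_single", "run_experiment", "simulate_session"]

SCHEMA_NAMES = ("graph", "simplicial", "mereological", "rcc5")


@dataclass
class ExperimentConfig:
    environment: dict = field(default_factory=lambda: {"kind": "arena-with-hole"})
    n_cells: int = 200
    f_mean: float = 12.0  # Hz
    s_mean: float = 0.2  # m (field size)
    cv: float = 0.3
    duration: float = 1500.0  # s
    mean_speed: float = 0.2  # m/s
    dt: float = 0.01  # s
    theta_freq: float = 8.0  # Hz
    theta_depth: float = 1.0
    seeds: tuple[int, ...] = tuple(range(1, 11))
    schemas: tuple[str, ...] = SCHEMA_NAMES
    track_cells: bool = False  # deterministic fields tiling a track
    track_spacing: float = 0.3  # m
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name, val in (
            ("n_cells", self.n_cells), ("f_mean", self.f_mean), ("s_mean", self.s_mean),
            ("duration", self.duration), ("mean_speed", self.mean_speed),
            ("dt", self.dt), ("theta_freq", self.theta_freq),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.seeds:
            raise ValueError("at least one seed is required")
        unknown = set(self.schemas) - set(SCHEMA_NAMES)
        if unknown:
            raise ValueError(f"unknown schemas: {sorted(unknown)}")
        if not self.schemas:
            raise ValueError("at least one schema must be enabled")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seeds" in data:
            data["seeds"] = tuple(data["seeds"])
        if "schemas" in data:
            data["schemas"] = tuple(data["schemas"])
        return cls(**data)


def _sub_seeds(seed: int, n: int = 3) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def simulate_session(config: ExperimentConfig, seed: int):
    """Simulate one session: returns (env, ensemble, trajectory, trains)."""
    env = build_environment(config.environment)
    traj_ss, ens_ss, spike_ss = _sub_seeds(seed)
    traj = simulate_trajectory(env, config.duration, config.mean_speed, config.dt, seed=traj_ss)
    if config.track_cells:
        if env.skeleton is None:
            raise ValueError("track_cells requires a track environment")
        ensemble = track_place_cells(env, spacing=config.track_spacing, peak_rate=config.f_mean)
    else:
        ensemble = sample_ensemble(env, config.n_cells, config.f_mean, config.s_mean,
                                   config.cv, seed=ens_ss)
    trains = generate_spikes(ensemble, traj, config.theta_freq, config.theta_depth, seed=spike_ss)
    return env, ensemble, traj, trains


def run_single(config: ExperimentConfig, seed: int, rcc5_init: str = "dr") -> dict:
    """Run one seed end to end; returns a nested report dict with the
    fitted learners attached under ``"learners"``."""
    env, ensemble, traj, trains = simulate_session(config, seed)
    report: dict = {"seed": seed, "learners": {}, "env_kind": env.kind}
    if "graph" in config.schemas:
        g = GraphSchema().fit(trains)
        report["graph"] = g.report()
        report["learners"]["graph"] = g
    if "simplicial" in config.schemas:
        s = SimplicialSchema().fit(trains)
        report["simplicial"] = s.report()
        report["learners"]["simplicial"] = s
    if "mereological" in config.schemas:
        m = MereologicalSchema(dt=config.dt).fit(trains)
        report["mereological"] = m.report()
        report["learners"]["mereological"] = m
    if "rcc5" in config.schemas:
        r = RCC5Schema(init=rcc5_init, seed=seed).fit(trains)
        report["rcc5"] = r.report()
        report["learners"]["rcc5"] = r
        if config.track_cells:
            tr = r.track_report()
            report["rcc5"]["track"] = {
                "classification": tr.classification,
                "overlap_degree": tr.overlap_degree,
                "stabilized_at": tr.stabilized_at,
                "n_endpoints": tr.count("endpoint"),
                "n_midpoints": tr.count("midpoint"),
                "n_junctions": tr.count("junction"),
            }
    report["trains"] = trains
    return report


_SCALARS = {
    "graph": ["t_n_s", "t_min_s", "frac_links_at_t_min", "entropy_bits", "n_edges"],
    "simplicial": ["t_min_s", "t_n_s", "max_order", "n_surviving_loops", "n_maximal"],
    "mereological": ["n_detected", "n_surviving", "majority_violation_time_s"],
    "rcc5": ["entropy_bits", "t_n_s", "n_changes"],
}


def run_experiment(config: ExperimentConfig, keep_learners: bool = False) -> dict:
    """Run all configured seeds and aggregate scalar outcomes.

    Returns ``{"per_seed": [...], "aggregate": {...}, "config": {...}}``;
    aggregate entries are ``{"median": ..., "iqr": [q25, q75],
    "values": [...]}`` per scalar.  If ``config.outdir`` is set, the
    report is also written as JSON.
    """
    per_seed = []
    for seed in config.seeds:
        rep = run_single(config, seed)
        if not keep_learners:
            rep.pop("learners", None)
            rep.pop("trains", None)
        per_seed.append(rep)
    aggregate: dict = {}
    for schema, keys in _SCALARS.items():
        if schema not in config.schemas:
            continue
        aggregate[schema] = {}
        for key in keys:
            vals = [r[schema].get(key) for r in per_seed if schema in r]
            vals = [v for v in vals if v is not None]
            if not vals:
                continue
            arr = np.array(vals, float)
            aggregate[schema][key] = {
                "median": float(np.median(arr)),
                "iqr": [float(np.percentile(arr, 25)), float(np.percentile(arr, 75))],
                "values": [float(v) for v in arr],
            }
    out = {"config": _config_dict(config), "per_seed": per_seed, "aggregate": aggregate}
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        serializable = {
            "config": out["config"],
            "per_seed": [{k: v for k, v in r.items() if k not in ("learners", "trains")}
                         for r in per_seed],
            "aggregate": aggregate,
        }
        with open(outdir / "experiment.json", "w") as fh:
            json.dump(serializable, fh, indent=1, default=str)
    return out


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["seeds"] = list(d["seeds"])
    d["schemas"] = list(d["schemas"])
    return d


# ---------------------------------------------------------------------------
# schema-vs-map relationship streams (for entropy / MI curves)
# ---------------------------------------------------------------------------

def relation_label_streams(trains, fmap, kind: str, graph=None, rcc5=None):
    """Aligned per-window relationship labels in the schema and the map.

    For every coactivity window the *schema* label and the *map* label
    of the currently ignited cells are reported: for the graph schema,
    the learned/actual connectivity of the lexicographically first
    active pair; for the simplicial schema, the coactivity order vs the
    overlap order of the reconstructed regions; for RCC5, the pair's
    current guess vs the polygon relation.

    Returns ``(times, schema_labels, map_labels)``.
    """
    window = coactivity_window(trains.theta_freq)
    events = detect_coactivity(trains, window)
    times, schema_labels, map_labels = [], [], []
    if kind == "rcc5":
        if rcc5 is None:
            raise ValueError("rcc5 learner required")
        changes = []
        for (i, j), steps in rcc5.state_.history.items():
            for t, old, new in steps:
                changes.append((t, (i, j), new))
        changes.sort(key=lambda c: c[0])
        current: dict[tuple[int, int], str] = {}
        k = 0
        poly_cache: dict[tuple[int, int], str] = {}
    for ev in events:
        cells = sorted(ev.cells)
        pair = (cells[0], cells[1])
        t = ev.t_start + window
        if kind == "graph":
            if graph is None:
                raise ValueError("graph learner required")
            if pair[0] not in fmap.regions or pair[1] not in fmap.regions:
                continue
            learned = graph.graph_.edge_times.get(pair)
            schema_labels.append(1 if learned is not None and learned <= ev.t_start else 0)
            map_labels.append(
                1 if fmap.regions[pair[0]].intersects(fmap.regions[pair[1]]) else 0
            )
        elif kind == "simplicial":
            schema_labels.append(len(ev.cells))
            map_labels.append(_map_overlap_order(fmap, trains, ev, window))
        elif kind == "rcc5":
            while k < len(changes) and changes[k][0] <= t:
                current[changes[k][1]] = changes[k][2]
                k += 1
            schema_labels.append(current.get(pair, "DR"))
            if pair not in poly_cache:
                if pair[0] in fmap.regions and pair[1] in fmap.regions:
                    poly_cache[pair] = polygon_rcc5(fmap.regions[pair[0]], fmap.regions[pair[1]])
                else:
                    poly_cache[pair] = "DR"
            map_labels.append(poly_cache[pair])
        else:
            raise ValueError(f"unknown stream kind: {kind}")
        times.append(t)
    return np.array(times), schema_labels, map_labels


def _map_overlap_order(fmap, trains, event, window) -> int:
    import shapely

    # position: first spike of the lexicographically first active cell
    for cid in sorted(event.cells):
        t = trains.times[cid]
        idx = np.searchsorted(t, event.t_start)
        if idx < len(t) and t[idx] < event.t_start + window:
            pos = trains.positions[cid][idx]
            return int(
                sum(
                    1
                    for r in fmap.regions.values()
                    if shapely.contains_xy(r, pos[0], pos[1])
                )
            )
    return 0
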