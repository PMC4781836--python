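import numpy as np
import pytest

from placeschema import (
    build_environment,
    generate_spikes,
    sample_ensemble,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def arena():
    return build_environment()


@pytest.fixture(scope="session")
def long_trajectory(arena):
    """A full-length (25 min) default-arena trajectory, shared by the
    coverage, speed and rate-map tests."""
    return simulate_trajectory(arena, duration=1500.0, seed=11)


@pytest.fixture(scope="session")
def small_session(arena, long_trajectory):
    """A 25-min session with a small (30-cell) ensemble for
    integration-level checks that need realistic occupancy."""
    ens = sample_ensemble(arena, n=30, seed=5)
    trains = generate_spikes(ens, long_trajectory, seed=7)
    return ens, long_trajectory, trains


def make_trains(times: dict, duration: float, theta_freq: float = 8.0, n_cells=None):
    """Assemble a SpikeTrains object from raw per-cell spike-time lists."""
    from placeschema.place_cells import SpikeTrains

    times = {cid: np.asarray(t, float) for cid, t in times.items()}
    positions = {cid: np.zeros((len(t), 2)) for cid, t in times.items()}
    return SpikeTrains(
        times=times,
        positions=positions,
        duration=duration,
        theta_freq=theta_freq,
        n_cells=n_cells if n_cells is not None else (max(times) + 1 if times else 0),
    )
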