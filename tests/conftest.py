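import numpy as np
import pytest

from crosstol.network import fit_all_pairs
from crosstol.simulate import generate_network, simulate_timecourse
from crosstol.ssystem import SSystemParams, Trajectory, simulate_pair

#: Seed of the standing network-recovery benchmark (10 nodes, 12 edges).
BENCHMARK_SEED = 42


@pytest.fixture(scope="session")
def times8():
    return np.linspace(0.0, 21.0, 8)


@pytest.fixture(scope="session")
def pulse_regulator(times8):
    """A transient (rise-then-relax) regulator profile."""
    values = 1.0 + 2.5 * np.exp(-(((times8 - 8.0) / 4.0) ** 2))
    return Trajectory("A", times8, values, "WS+HS")


@pytest.fixture(scope="session")
def known_edge_target(times8, pulse_regulator):
    """Target simulated noiselessly from the pulse regulator with known
    kinetics (alpha=1.5, beta=0.8, g=1.2, h=1)."""
    params = SSystemParams(alpha=1.5, beta=0.8, g=1.2, h=1.0)
    sim = simulate_pair(params, pulse_regulator, 1.0, times8)
    return params, Trajectory("B", times8, sim.values, "WS+HS")


@pytest.fixture(scope="session")
def benchmark_sweep():
    """One full all-pairs fit of the 10-node / 12-edge noisy benchmark.

    Expensive (minutes); shared session-wide by the recovery property test
    and the acceptance checks.
    """
    network = generate_network(10, 12, seed=BENCHMARK_SEED)
    trajectories = simulate_timecourse(
        network, noise_cv=0.02, seed=BENCHMARK_SEED
    )
    candidates = fit_all_pairs(trajectories)
    return network, trajectories, candidates
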