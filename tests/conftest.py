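import numpy as np
import pytest

from rclpsd.params import SimulationParameters
from rclpsd.state import SystemState
from rclpsd.topology import Topology, make_topology


@pytest.fixture
def params():
    """Default Kremer-Grest parameters in a 10-sigma periodic box."""
    return SimulationParameters(box_side=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_small_system(n_mon, n_mol, n_c, n_bs, box, seed, spread=2.5):
    """Compact random configuration without hard overlaps, for force oracles."""
    rng = np.random.default_rng(seed)
    topo = make_topology(n_mon=n_mon, n_mol=n_mol, n_c=n_c, n_bs=n_bs, rng=rng)
    n = n_mon + n_mol
    # chain with ~unit bonds, molecules scattered nearby; keep pairs >= 0.85 sigma
    pos = np.empty((n, 3))
    pos[0] = box / 2.0
    for i in range(1, n_mon):
        while True:
            u = rng.normal(size=3)
            cand = pos[i - 1] + 0.97 * u / np.linalg.norm(u)
            d = pos[: max(0, i - 1)] - cand
            d -= box * np.round(d / box)
            if i < 2 or np.min(np.sum(d**2, axis=1)) > 0.85**2:
                pos[i] = cand
                break
    for m in range(n_mol):
        i = n_mon + m
        while True:
            cand = pos[0] + rng.uniform(-spread, spread, 3)
            d = pos[:i] - cand
            d -= box * np.round(d / box)
            if np.min(np.sum(d**2, axis=1)) > 0.9**2:
                pos[i] = cand
                break
    vel = rng.normal(size=(n, 3))
    state = SystemState(
        positions=pos, velocities=vel, box=box,
        bound_site=np.full(n_mol, -1, dtype=np.int64),
    )
    return state, topo
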