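"""System state and initial-configuration placement."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SimulationParameters
from .topology import Topology


@dataclass
class SystemState:
    """Positions/velocities of all beads plus the molecule->site bond registry.

    Positions are stored unwrapped; ``wrapped()``/``images()`` derive the
    in-box coordinates and periodic image flags.  ``bound_site[m]`` is the
    monomer index the m-th molecule is attached to, or -1 when free (each
    molecule binds at most one site; a site may hold several molecules).
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: float
    time: float = 0.0
    bound_site: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.shape != self.velocities.shape or self.positions.shape[1] != 3:
            raise ValueError("positions and velocities must both have shape (N, 3)")
        if self.bound_site is None:
            self.bound_site = np.full(0, -1, dtype=np.int64)
        self.bound_site = np.ascontiguousarray(self.bound_site, dtype=np.int64)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def images(self) -> np.ndarray:
        return np.floor(self.positions / self.box).astype(np.int64)

    def wrapped(self) -> np.ndarray:
        return self.positions - self.box * np.floor(self.positions / self.box)

    def kinetic_temperature(self, mass: float = 1.0) -> float:
        """Instantaneous kinetic temperature m<v^2>/3 per particle."""
        return mass * float(np.mean(np.sum(self.velocities**2, axis=1))) / 3.0

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=self.box,
            time=self.time,
            bound_site=self.bound_site.copy(),
        )


def maxwell_velocities(
    n: int, kT: float, mass: float, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell-Boltzmann draw with the center-of-mass drift removed."""
    v = rng.normal(0.0, np.sqrt(kT / mass), size=(n, 3))
    if n > 1:
        v -= v.mean(axis=0)
    return v


def place_initial_configuration(
    params: SimulationParameters,
    topology: Topology,
    rng: np.random.Generator | int,
    bond_length: float | None = None,
    min_separation: float | None = None,
    max_tries: int = 2000,
) -> SystemState:
    """Self-avoiding-walk chain layout plus rejection-sampled molecule insertion.

    The chain grows with fixed bond length (default the WCA+FENE minimum,
    ~0.96 sigma) rejecting steps that come within 0.9 sigma of a previous
    monomer; molecules are inserted uniformly with every pair distance
    >= min_separation (default sigma).  Velocities are Maxwell-Boltzmann.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = params.box_side
    if bond_length is None:
        # minimum of WCA + FENE for the default Kremer-Grest constants
        from scipy.optimize import minimize_scalar

        def u(r):
            sr6 = (params.sigma / r) ** 6
            wca = 4 * params.epsilon * (sr6**2 - sr6 + 0.25) if r <= params.r_cut else 0.0
            return wca - 0.5 * params.kappa_fene * params.R0**2 * np.log1p(-((r / params.R0) ** 2))

        bond_length = float(minimize_scalar(u, bounds=(0.5, params.R0 * 0.99), method="bounded").x)
    if min_separation is None:
        min_separation = params.sigma

    n_mon, n_mol = topology.n_mon, topology.n_mol
    pos = np.empty((n_mon + n_mol, 3))
    pos[0] = rng.uniform(0.25 * L, 0.75 * L, size=3)
    self_avoid = 0.9 * params.sigma
    for i in range(1, n_mon):
        for attempt in range(max_tries):
            step = rng.normal(size=3)
            step *= bond_length / np.linalg.norm(step)
            cand = pos[i - 1] + step
            delta = pos[: max(0, i - 1)] - cand
            delta -= L * np.round(delta / L)  # periodic images overlap too
            if delta.size == 0 or np.min(np.sum(delta**2, axis=1)) >= self_avoid**2:
                pos[i] = cand
                break
        else:
            raise RuntimeError(f"could not grow SAW chain at monomer {i}")

    for m in range(n_mol):
        i = n_mon + m
        for attempt in range(max_tries):
            cand = rng.uniform(0.0, L, size=3)
            delta = pos[:i] - cand
            delta -= L * np.round(delta / L)
            if np.min(np.sum(delta**2, axis=1)) >= min_separation**2:
                pos[i] = cand
                break
        else:
            raise RuntimeError(f"could not insert molecule {m}: box too crowded")

    vel = maxwell_velocities(n_mon + n_mol, params.kT, params.mass, rng)
    return SystemState(
        positions=pos,
        velocities=vel,
        box=L,
        time=0.0,
        bound_site=np.full(n_mol, -1, dtype=np.int64),
    )
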