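"""Force field of the generalized random cross-linker (RCL) polymer model.

Energy terms (reduced LJ units):

- ``lj_energy``        truncated-and-shifted (WCA) repulsion between any two
                       beads, cutoff at the LJ minimum 2^(1/6) sigma;
- ``fene_energy``      finitely extensible backbone bond, divergent at R0;
- ``bending_energy``   kappa_theta * (1 - cos theta) on consecutive bonds;
- ``crosslink_energy`` harmonic spring of a random cross-linker;
- ``binding_energy``   full truncated LJ of depth eps_bind between a molecule
                       and the binding site it is attached to.

``total_energy``/``forces`` assemble the full Hamiltonian over a periodic
box: WCA over every pair within cutoff (minimum image), FENE over backbone
bonds, bending over interior monomers, harmonic springs over cross-links and
the attractive well over registered molecule-site bonds.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .params import SimulationParameters
from .state import SystemState
from .topology import Topology


class OverstretchedBondError(RuntimeError):
    """A FENE backbone bond reached or exceeded its maximum extension R0."""


def lj_energy(r: float, params: SimulationParameters) -> float:
    """WCA pair energy: 4*eps*[(s/r)^12 - (s/r)^6 + 1/4] for r <= 2^(1/6)s."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sr6 = (params.sigma / r) ** 6
    e = 4.0 * params.epsilon * (sr6**2 - sr6 + 0.25)
    return np.where(r <= params.r_cut, e, 0.0)[()]


def fene_energy(r: float, params: SimulationParameters) -> float:
    """FENE bond energy -0.5*k*R0^2*ln(1 - (r/R0)^2); infinite at r >= R0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(r >= params.R0):
        raise OverstretchedBondError(f"FENE bond at r >= R0 = {params.R0}")
    return (-0.5 * params.kappa_fene * params.R0**2 * np.log1p(-((r / params.R0) ** 2)))[()]


def bending_energy(r_prev, r_mid, r_next, params: SimulationParameters) -> float:
    """kappa_theta * (1 - cos theta) between consecutive bond vectors."""
    b1 = np.asarray(r_mid, float) - np.asarray(r_prev, float)
    b2 = np.asarray(r_next, float) - np.asarray(r_mid, float)
    n1 = np.linalg.norm(b1)
    n2 = np.linalg.norm(b2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero-length bond vector in bending term")
    return params.kappa_theta * (1.0 - float(b1 @ b2) / (n1 * n2))


def crosslink_energy(r: float, params: SimulationParameters) -> float:
    """Harmonic cross-linker energy (k_rc/2) r^2 (zero rest length)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    return (0.5 * params.k_rc * r**2)[()]


def binding_energy(r: float, params: SimulationParameters) -> float:
    """Attractive molecule-site LJ (depth eps_bind), truncated-shifted at bind_cut*sigma."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sr6 = (params.sigma / r) ** 6
    rc = params.bind_cut * params.sigma
    src6 = (params.sigma / rc) ** 6
    shift = 4.0 * params.eps_bind * (src6**2 - src6)
    e = 4.0 * params.eps_bind * (sr6**2 - sr6) - shift
    return np.where(r <= rc, e, 0.0)[()]


def _pair_list(state: SystemState, params: SimulationParameters) -> tuple[np.ndarray, int]:
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    maxpairs = 60 * len(pos) + 1024
    while True:
        pairs = np.empty((maxpairs, 2), np.int32)
        n = _kernels.build_pair_list(pos, params.box_side, params.r_cut, pairs)
        if n >= 0:
            return pairs, n
        maxpairs *= 4


def total_energy(state: SystemState, topology: Topology, params: SimulationParameters) -> float:
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    pairs, n_pairs = _pair_list(state, params)
    e, status = _kernels.compute_energy(
        pos, topology.n_mon, pairs, n_pairs,
        topology.cross_links, state.bound_site, params.box_side,
        params.sigma, params.epsilon, params.R0, params.kappa_fene,
        params.kappa_theta, params.k_rc, params.eps_bind,
        params.bind_cut * params.sigma,
    )
    if status == _kernels.STATUS_OVERSTRETCH:
        raise OverstretchedBondError("FENE bond at r >= R0")
    return float(e)


def forces(state: SystemState, topology: Topology, params: SimulationParameters) -> np.ndarray:
    """Analytic forces -grad H on every particle, shape (N, 3)."""
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    pairs, n_pairs = _pair_list(state, params)
    frc = np.empty_like(pos)
    status = _kernels.compute_forces(
        pos, frc, topology.n_mon, pairs, n_pairs,
        topology.cross_links, state.bound_site, params.box_side,
        params.sigma, params.epsilon, params.R0, params.kappa_fene,
        params.kappa_theta, params.k_rc, params.eps_bind,
        params.bind_cut * params.sigma,
    )
    if status == _kernels.STATUS_OVERSTRETCH:
        raise OverstretchedBondError("FENE bond at r >= R0")
    return frc
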