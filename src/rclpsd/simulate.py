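"""Langevin dynamics driver: single steps, binding bookkeeping, full runs.

Integration uses the Gronbech-Jensen/Farago discretization of Langevin
velocity Verlet, which samples the configurational Boltzmann distribution
correctly at finite time step and reduces to plain velocity Verlet (NVE)
when the friction is zero.
"""

from __future__ import annotations

import logging

import numpy as np

from . import _kernels
from .forcefield import OverstretchedBondError
from .params import SimulationParameters, SimulationProtocol
from .state import SystemState, place_initial_configuration
from .topology import Topology
from .trajectory import TrajectoryEnsemble

log = logging.getLogger(__name__)


class SimulationBlowupError(RuntimeError):
    """Non-finite coordinates appeared; the diagnostic state is attached."""

    def __init__(self, msg: str, state: SystemState | None = None):
        super().__init__(msg)
        self.state = state


def _kernel_args(topology: Topology, params: SimulationParameters):
    return dict(
        n_mon=topology.n_mon,
        cross_links=np.ascontiguousarray(topology.cross_links, dtype=np.int64),
        sites=np.ascontiguousarray(topology.binding_sites, dtype=np.int64),
        L=params.box_side,
        sigma=params.sigma,
        eps=params.epsilon,
        mass=params.mass,
        R0=params.R0,
        kfene=params.kappa_fene,
        ktheta=params.kappa_theta,
        krc=params.k_rc,
        epsb=params.eps_bind,
        bindcut=params.bind_cut * params.sigma,
        gamma=params.gamma_damp,
        dt=params.dt,
        kT=params.kT,
        dcap=params.d_capture,
    )


_CHUNK_STEPS = 2500  # noise pre-generation granularity; fixed so runs are reproducible


def _integrate(
    state: SystemState,
    ka: dict,
    n_steps: int,
    frame_interval: int,
    frames: np.ndarray,
    times: np.ndarray,
    registry: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Drive the kernel in fixed-size chunks with numpy-generated noise."""
    N = state.n_particles
    amp = np.sqrt(2.0 * ka["gamma"] * ka["mass"] * ka["kT"] * ka["dt"])
    step0 = 0
    while step0 < n_steps:
        n = min(_CHUNK_STEPS, n_steps - step0)
        if amp > 0.0:
            noise = amp * rng.standard_normal((n, N, 3))
        else:
            noise = np.zeros((n, N, 3))
        status = _kernels.run_chunk(
            state.positions, state.velocities,
            ka["n_mon"], ka["cross_links"], ka["sites"], state.bound_site,
            ka["L"], ka["sigma"], ka["eps"], ka["mass"], ka["R0"], ka["kfene"],
            ka["ktheta"], ka["krc"], ka["epsb"], ka["bindcut"], ka["gamma"],
            ka["dt"], ka["dcap"],
            noise, step0, frame_interval, frames, times, registry, 0.0,
        )
        _raise_on_status(status, state)
        step0 += n


def update_bindings(
    state: SystemState, topology: Topology, params: SimulationParameters
) -> SystemState:
    """Apply the capture/release rule in place and return the state.

    A free molecule within ``d_capture`` of any site attaches to the nearest
    one (ties to the lowest site index); a bound molecule farther than
    ``d_capture`` from its site is released.  One site per molecule; a site
    may hold any number of molecules.
    """
    if topology.n_bs == 0:
        return state
    _kernels.update_bindings_kernel(
        state.positions,
        topology.n_mon,
        np.ascontiguousarray(topology.binding_sites, dtype=np.int64),
        state.bound_site,
        params.box_side,
        params.d_capture,
    )
    return state


def step(
    state: SystemState,
    topology: Topology,
    params: SimulationParameters,
    rng: np.random.Generator | int | None = None,
    n_steps: int = 1,
) -> SystemState:
    """Advance the state in place by ``n_steps`` Langevin velocity-Verlet steps."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ka = _kernel_args(topology, params)
    _integrate(
        state, ka, n_steps, max(n_steps, 1),
        np.empty((0, state.n_particles, 3)), np.empty(0), np.empty((0, 0), np.int64),
        rng,
    )
    state.time += n_steps * params.dt
    return state


def _raise_on_status(status: int, state: SystemState | None = None) -> None:
    if status == _kernels.STATUS_OVERSTRETCH:
        raise OverstretchedBondError("FENE bond overstretched during integration")
    if status == _kernels.STATUS_NONFINITE:
        raise SimulationBlowupError("non-finite coordinates (numerical blow-up)", state)
    if status == _kernels.STATUS_OVERFLOW:
        raise SimulationBlowupError("neighbor-list overflow (density too high?)", state)


def run(
    params: SimulationParameters,
    topology: Topology,
    protocol: SimulationProtocol,
    state: SystemState | None = None,
    realization_id: int | None = None,
) -> TrajectoryEnsemble:
    """Equilibrate then record a production trajectory.

    Fully deterministic for a fixed (seed, parameters, topology): the
    initial configuration, equilibration noise and production noise are all
    derived from ``protocol.seed``.
    """
    rng = np.random.default_rng(protocol.seed)
    if state is None:
        state = place_initial_configuration(params, topology, rng)
    rho = params.density(topology.n_particles)
    log.info(
        "run seed=%d N_mon=%d N_mol=%d N_c=%d rho=%.4g box=%.4g",
        protocol.seed, topology.n_mon, topology.n_mol, topology.n_c, rho, params.box_side,
    )
    ka = _kernel_args(topology, params)
    if protocol.n_equil_steps:
        _integrate(
            state, ka, protocol.n_equil_steps, protocol.n_equil_steps,
            np.empty((0, state.n_particles, 3)), np.empty(0), np.empty((0, 0), np.int64),
            rng,
        )

    n_frames = protocol.n_frames
    frames = np.empty((n_frames, state.n_particles, 3))
    times = np.empty(n_frames)
    registry = np.full((n_frames if topology.n_mol else 0, topology.n_mol), -1, np.int64)
    if protocol.n_prod_steps:
        _integrate(
            state, ka, protocol.n_prod_steps, protocol.frame_interval,
            frames, times, registry, rng,
        )
    state.time = (protocol.n_equil_steps + protocol.n_prod_steps) * params.dt
    return TrajectoryEnsemble(
        frames=frames,
        times=times,
        box=params.box_side,
        topology=topology,
        params=params,
        registry=registry if topology.n_mol else None,
        seed=protocol.seed,
        realization_id=realization_id,
    )
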