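"""Physical parameters and run protocols in reduced Lennard-Jones units.

All quantities are expressed in reduced units: the monomer/molecule diameter
``sigma`` is the unit of length (mapping to 30 nm of 30-nm chromatin fiber,
one bead = 3 kbp), the thermal energy ``epsilon = k_B T`` (T = 300 K) is the
unit of energy, and the bead mass is the unit of mass.  The intrinsic time
scale is ``tau_MD = sigma * sqrt(mass / epsilon)`` which calibrates to about
0.02 s for semi-dilute chromatin solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


@dataclass
class SimulationParameters:
    """Force-field coefficients and integration settings.

    Defaults follow the Kremer-Grest bead-spring parameterization with a
    harmonic cross-linker spring and an attractive binding-site well:

    - truncated-shifted (WCA) Lennard-Jones with cutoff ``2^(1/6) sigma``,
    - FENE backbone with ``R0 = 1.5 sigma``, ``kappa_fene = 30 eps/sigma^2``,
    - bending stiffness ``kappa_theta = 5 k_B T`` (Kuhn length ~10 beads),
    - cross-link springs ``k_rc = 0.5 eps/sigma^2``,
    - molecule/binding-site attraction of depth ``5 k_B T`` acting below a
      capture distance ``2 * 2^(1/6) sigma``,
    - Langevin friction ``gamma = 0.5 / tau_MD``, time step ``5e-3 tau_MD``.
    """

    sigma: float = 1.0
    epsilon: float = 1.0
    mass: float = 1.0
    R0: float = 1.5
    kappa_fene: float = 30.0
    kappa_theta: float = 5.0
    k_rc: float = 0.5
    eps_bind: float = 5.0
    bind_cut: float = 2.5
    gamma_damp: float = 0.5
    dt: float = 5e-3
    box_side: float = 10.0
    kT: float = 1.0

    @property
    def r_cut(self) -> float:
        """WCA cutoff: the LJ minimum, ``2^(1/6) sigma``."""
        return 2.0 ** (1.0 / 6.0) * self.sigma

    @property
    def d_capture(self) -> float:
        """Molecule-to-binding-site capture distance, ``2 * 2^(1/6) sigma``."""
        return 2.0 * 2.0 ** (1.0 / 6.0) * self.sigma

    @property
    def tau_MD(self) -> float:
        return self.sigma * math.sqrt(self.mass / self.epsilon)

    @property
    def diffusion_coefficient(self) -> float:
        """Free-particle diffusion coefficient ``D = kT / (m gamma)``."""
        return self.kT / (self.mass * self.gamma_damp)

    def __post_init__(self) -> None:
        for name in ("sigma", "epsilon", "mass", "R0", "dt", "box_side", "kT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt >= self.tau_MD:
            raise ValueError("dt must be smaller than tau_MD")

    def density(self, n_particles: int) -> float:
        return n_particles / self.box_side**3

    @classmethod
    def from_density(cls, n_particles: int, rho: float, **kwargs) -> "SimulationParameters":
        """Build parameters with the box side set so (N_mon+N_mol)/V = rho."""
        if not (rho > 0):
            raise ValueError("rho must be positive")
        box = (n_particles / rho) ** (1.0 / 3.0)
        return cls(box_side=box, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationProtocol:
    """Equilibration/production schedule and ensemble sizes.

    The reference study conditions are ``n_equil_steps = 10**6``,
    ``n_prod_steps = 5 * 10**6`` (2.5e4 tau_MD at dt = 5e-3), 100 cross-link
    realizations with 100 runs each; desk-scale analyses pass smaller values.
    """

    n_equil_steps: int = 1_000_000
    n_prod_steps: int = 5_000_000
    frame_interval: int = 200
    n_realizations: int = 100
    n_runs_per_realization: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_equil_steps < 0 or self.n_prod_steps < 0:
            raise ValueError("step counts must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_prod_steps % self.frame_interval != 0:
            raise ValueError("frame_interval must divide n_prod_steps")

    @property
    def n_frames(self) -> int:
        return self.n_prod_steps // self.frame_interval
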