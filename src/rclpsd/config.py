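"""Run configuration: schema-validated YAML, defaults filled from the
standard study conditions (dt = 5e-3 tau_MD, 1e6 equilibration steps,
5e6 production steps, frame every 200 steps)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .params import SimulationParameters, SimulationProtocol


class ParametersConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rho: float = Field(gt=0, description="total number density (N_mon+N_mol)/V")
    sigma: float = Field(default=1.0, gt=0)
    epsilon: float = Field(default=1.0, gt=0)
    mass: float = Field(default=1.0, gt=0)
    R0: float = Field(default=1.5, gt=0)
    kappa_fene: float = Field(default=30.0, gt=0)
    kappa_theta: float = Field(default=5.0, ge=0)
    k_rc: float = Field(default=0.5, ge=0)
    eps_bind: float = Field(default=5.0, ge=0)
    bind_cut: float = Field(default=2.5, gt=0)
    gamma_damp: float = Field(default=0.5, ge=0)
    dt: float = Field(default=5e-3, gt=0)
    kT: float = Field(default=1.0, gt=0)


class TopologyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_mon: int = Field(ge=1)
    n_mol: int = Field(default=0, ge=0)
    n_c: int = Field(default=0, ge=0)
    n_bs: int = Field(default=0, ge=0)


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_equil_steps: int = Field(default=1_000_000, ge=0)
    n_prod_steps: int = Field(default=5_000_000, ge=0)
    frame_interval: int = Field(default=200, ge=1)
    n_realizations: int = Field(default=100, ge=1)
    n_runs_per_realization: int = Field(default=100, ge=1)
    seed: int = 0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    parameters: ParametersConfig
    topology: TopologyConfig
    protocol: ProtocolConfig = ProtocolConfig()
    output_prefix: str = "run"

    def simulation_parameters(self) -> SimulationParameters:
        p = self.parameters
        n = self.topology.n_mon + self.topology.n_mol
        return SimulationParameters.from_density(
            n,
            p.rho,
            sigma=p.sigma,
            epsilon=p.epsilon,
            mass=p.mass,
            R0=p.R0,
            kappa_fene=p.kappa_fene,
            kappa_theta=p.kappa_theta,
            k_rc=p.k_rc,
            eps_bind=p.eps_bind,
            bind_cut=p.bind_cut,
            gamma_damp=p.gamma_damp,
            dt=p.dt,
            kT=p.kT,
        )

    def simulation_protocol(self, seed: int | None = None) -> SimulationProtocol:
        pr = self.protocol
        return SimulationProtocol(
            n_equil_steps=pr.n_equil_steps,
            n_prod_steps=pr.n_prod_steps,
            frame_interval=pr.frame_interval,
            n_realizations=pr.n_realizations,
            n_runs_per_realization=pr.n_runs_per_realization,
            seed=pr.seed if seed is None else seed,
        )


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    data = yaml.safe_load(p.read_text()) or {}
    return RunConfig.model_validate(data)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
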