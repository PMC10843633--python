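"""Condition sweeps over the cross-linker number N_c.

Runs the simulator over several quenched cross-link realizations per
condition and aggregates the headline observables: mean gyration radius,
molecule occupancy of the PSD interior, the anomalous-exponent spectrum
inside the domain, the parabolic index of the reconstructed drift field,
and optionally the mesh size.  Desk-scale problem sizes (small chains,
short runs) reproduce the qualitative trends of the full-scale ensembles.

Two analysis conventions matter here:

- the anomalous exponent is fitted for lag times past the thermostat's
  velocity relaxation (window [5, 50] tau_MD by default, vs 1/gamma =
  2 tau_MD), so it measures configurational diffusion rather than the
  ballistic-to-diffusive crossover of the underdamped dynamics;
- the drift field is pooled over all realizations of a condition before
  computing the parabolic index S (bins out to 1.5 <R_g> around the CM),
  mirroring the ensemble averaging of the reference analysis and keeping
  per-bin occupancy high even when the condensed domain excludes most
  molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kinetics import anomalous_exponent, conditional_msd
from .params import SimulationParameters, SimulationProtocol
from .simulate import run
from .structure import (
    PSDRegion,
    mean_gyration_radius,
    molecule_coords_rel_cm,
    pore_size_distribution,
)
from .topology import make_topology
from .wellfield import bin_drift_samples, grid_from_sums, parabolic_index

log = logging.getLogger(__name__)

MSD_WINDOW = (5.0, 50.0)  # tau_MD; past the 1/gamma inertial crossover


@dataclass
class RealizationResult:
    n_c: int
    rg: float
    occupancy: float
    alpha_inside: float
    zeta: float = np.nan


@dataclass
class ConditionResult:
    """Aggregate over cross-link realizations at one N_c."""

    n_c: int
    realizations: list
    S_pooled: float = np.nan

    def _agg(self, attr: str) -> tuple[float, float]:
        v = np.array([getattr(r, attr) for r in self.realizations], dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return np.nan, np.nan
        se = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        return float(np.mean(v)), se

    @property
    def rg(self):
        return self._agg("rg")

    @property
    def occupancy(self):
        return self._agg("occupancy")

    @property
    def alpha_inside(self):
        return self._agg("alpha_inside")

    @property
    def zeta(self):
        return self._agg("zeta")

    @property
    def S(self):
        return (self.S_pooled, np.nan)


def analyze_run(
    ens, msd_window=MSD_WINDOW, pore_probes: int = 0, pore_rng=0
) -> RealizationResult:
    """Single-run observables relative to the per-realization PSD region."""
    rg = mean_gyration_radius(ens)
    region = PSDRegion(radius=rg)
    rel = molecule_coords_rel_cm(ens)  # (F, n_mol, 3), minimum-image folded
    r = np.linalg.norm(rel, axis=-1)
    # occupancy: molecules found inside Omega vs the uniform expectation
    v_frac = region.volume / ens.box**3
    occupancy = float(np.mean(r < rg) / v_frac)

    # displacements from unwrapped CM-relative coordinates (exact at any
    # lag); the conditioning radius uses the folded nearest-image distance
    rel_unwrapped = ens.molecule_frames() - ens.center_of_mass()[:, None, :]
    tracks = np.transpose(rel_unwrapped, (1, 0, 2))  # (n_mol, F, 3)
    frame_dt = float(np.mean(np.diff(ens.times)))
    max_lag = max(4, int(np.ceil(msd_window[1] / frame_dt)) + 1)
    cmsd = conditional_msd(
        tracks,
        ens.times,
        dr=rg / 10.0,
        lags=np.arange(1, max_lag + 1),
        r_max=2.0 * rg,
        radii=r.T,
    )
    spec = anomalous_exponent(cmsd, window=msd_window)
    alpha_inside = spec.mean_alpha_in(0.0, rg)

    zeta = np.nan
    if pore_probes > 0:
        mon_rel = ens.monomer_frames()[-1] - ens.center_of_mass()[-1]
        psd = pore_size_distribution(
            mon_rel, region_radius=rg, n_probes=pore_probes, rng=pore_rng
        )
        zeta = psd.mesh_size
    return RealizationResult(
        n_c=ens.topology.n_c, rg=rg, occupancy=occupancy,
        alpha_inside=alpha_inside, zeta=zeta,
    )


def drift_samples_rel_cm(ens):
    """(start, displacement-rate) samples of molecules in the CM frame."""
    rel = molecule_coords_rel_cm(ens)
    frame_dt = float(np.mean(np.diff(ens.times)))
    start = rel[:-1].reshape(-1, 3)
    d = (rel[1:] - rel[:-1]).reshape(-1, 3)
    d -= ens.box * np.round(d / ens.box)
    return start, d / frame_dt


def run_condition(
    n_c: int,
    n_mon: int = 200,
    n_mol: int = 400,
    rho: float = 0.05,
    n_realizations: int = 10,
    n_equil_steps: int = 50_000,
    n_prod_steps: int = 150_000,
    frame_interval: int = 200,
    seed: int = 0,
    n_bs: int = 0,
    pore_probes: int = 0,
) -> ConditionResult:
    """Run one N_c condition over several quenched cross-link realizations."""
    params = SimulationParameters.from_density(n_mon + n_mol, rho)
    results = []
    root = np.random.SeedSequence([seed, n_c])
    drift_acc = None
    frame_dt = frame_interval * params.dt
    for r, child in enumerate(root.spawn(n_realizations)):
        sub = np.random.default_rng(child)
        topo = make_topology(n_mon=n_mon, n_mol=n_mol, n_c=n_c, n_bs=n_bs, rng=sub)
        proto = SimulationProtocol(
            n_equil_steps=n_equil_steps,
            n_prod_steps=n_prod_steps,
            frame_interval=frame_interval,
            n_realizations=n_realizations,
            n_runs_per_realization=1,
            seed=int(sub.integers(0, 2**31 - 1)),
        )
        ens = run(params, topo, proto, realization_id=r)
        res = analyze_run(
            ens, pore_probes=pore_probes, pore_rng=int(sub.integers(0, 2**31 - 1))
        )
        results.append(res)
        # pooled drift field: grid fixed by the first realization's R_g
        if drift_acc is None:
            dx = res.rg / 5.0
            extent = 1.5 * res.rg
            nb = max(3, int(np.ceil(2 * extent / dx)))
            drift_acc = [np.zeros((nb**3, 3)), np.zeros(nb**3, dtype=np.int64), dx, nb]
        start, disp = drift_samples_rel_cm(ens)
        s, c = bin_drift_samples(start, disp, drift_acc[2], drift_acc[3])
        drift_acc[0] += s
        drift_acc[1] += c
        log.info("condition N_c=%d realization %d/%d done", n_c, r + 1, n_realizations)

    rg_mean = float(np.mean([x.rg for x in results]))
    try:
        grid = grid_from_sums(
            drift_acc[0], drift_acc[1], drift_acc[2], frame_dt, min_count=20
        )
        S_pooled = parabolic_index(grid.restrict(rg_mean))
    except ValueError:
        S_pooled = np.nan
    return ConditionResult(n_c=n_c, realizations=results, S_pooled=S_pooled)


def sweep_crosslinkers(n_c_values, seed: int = 0, **kwargs) -> list:
    """Run several N_c conditions; see :func:`run_condition` for sizes."""
    return [run_condition(n_c=nc, seed=seed, **kwargs) for nc in n_c_values]
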