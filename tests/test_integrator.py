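"""Langevin integrator: NVE limit, thermostat, Brownian limit, bindings,
initial configuration and reproducibility."""

import numpy as np
import pytest

from rclpsd import forcefield as ff
from rclpsd.params import SimulationParameters, SimulationProtocol
from rclpsd.simulate import run, step, update_bindings
from rclpsd.state import SystemState, place_initial_configuration
from rclpsd.topology import Topology, make_topology

from conftest import random_small_system


def total_e(state, topo, params):
    kin = 0.5 * params.mass * np.sum(state.velocities**2)
    return kin + ff.total_energy(state, topo, params)


class TestNVELimit:
    def _drift(self, state, topo, params, n_steps=1000):
        """Secular energy drift over n_steps: linear trend of per-step energy.

        Velocity Verlet conserves a shadow Hamiltonian, so the energy
        oscillates with amplitude O(dt^2 omega^2) but must not drift; the
        regression averages the oscillation out.
        """
        e = np.empty(n_steps)
        for k in range(n_steps):
            step(state, topo, params, rng=0, n_steps=1)
            e[k] = total_e(state, topo, params)
        slope = np.polyfit(np.arange(n_steps), e, 1)[0]
        return abs(slope) * n_steps, np.mean(np.abs(e))

    def test_two_body_energy_drift(self):
        """gamma = 0, no noise: two-body LJ drift < 1e-4 eps over 1e3 steps."""
        params = SimulationParameters(box_side=10.0, gamma_damp=0.0)
        pos = np.array([[5.0, 5, 5], [6.02, 5, 5]])
        vel = np.array([[0.05, 0.02, 0.0], [-0.05, -0.02, 0.0]])
        state = SystemState(pos, vel, box=10.0)
        topo = Topology(n_mon=2)
        drift, _ = self._drift(state, topo, params)
        assert drift < 1e-4

    def test_ten_particle_energy_drift(self, params):
        nve = SimulationParameters(box_side=params.box_side, gamma_damp=0.0)
        state, topo = random_small_system(6, 4, 2, 0, nve.box_side, seed=3)
        state.velocities *= 0.3
        drift, scale = self._drift(state, topo, nve)
        assert drift / scale < 1e-4


class TestThermostat:
    def test_free_particle_msd_slope(self):
        """Force-free particles obey MSD = 6 D tau with D = kT/(m gamma)."""
        n = 200
        params = SimulationParameters.from_density(n, 1e-4)  # essentially ideal
        topo = Topology(n_mon=1, n_mol=n - 1)
        proto = SimulationProtocol(
            n_equil_steps=2000, n_prod_steps=400_000, frame_interval=100, seed=5
        )
        ens = run(params, topo, proto)
        x = ens.frames  # (F, n, 3) unwrapped
        lag = 200  # frames = 100 tau_MD >> the velocity relaxation time 1/gamma
        disp2 = np.sum((x[lag:] - x[:-lag]) ** 2, axis=-1)
        tau = lag * 100 * params.dt
        D = params.diffusion_coefficient
        assert np.mean(disp2) == pytest.approx(6 * D * tau, rel=0.05)

    def test_equipartition_ideal_gas(self):
        """Dilute thermostatted gas: <KE>/particle = 3/2 kT within 2%."""
        n = 125
        params = SimulationParameters.from_density(n, 0.005)
        topo = Topology(n_mon=1, n_mol=n - 1)
        state = place_initial_configuration(params, topo, 7)
        ke = []
        rng = np.random.default_rng(17)
        step(state, topo, params, rng, n_steps=2000)  # burn-in
        for _ in range(60):
            step(state, topo, params, rng, n_steps=100)
            ke.append(0.5 * params.mass * np.sum(state.velocities**2) / n)
        assert np.mean(ke) == pytest.approx(1.5 * params.kT, rel=0.02)


class TestReproducibility:
    def test_identical_seeds_identical_trajectories(self):
        topo = make_topology(n_mon=20, n_mol=10, n_c=5, n_bs=2, rng=3)
        params = SimulationParameters.from_density(30, 0.05)
        proto = SimulationProtocol(n_equil_steps=500, n_prod_steps=1000, frame_interval=100, seed=11)
        a = run(params, topo, proto)
        b = run(params, topo, proto)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.registry, b.registry)

    def test_zero_production_steps(self):
        topo = make_topology(n_mon=5, n_mol=2, rng=0)
        params = SimulationParameters.from_density(7, 0.02)
        proto = SimulationProtocol(n_equil_steps=100, n_prod_steps=0, frame_interval=10, seed=1)
        ens = run(params, topo, proto)
        assert ens.n_frames == 0
        assert ens.topology.n_mon == 5


class TestBindings:
    def _setup(self, mol_pos, params):
        # binding sites at monomers 0 and 1, one molecule
        pos = np.array([[2.0, 2, 2], [6.0, 2, 2], list(mol_pos)])
        state = SystemState(pos, np.zeros_like(pos), box=params.box_side,
                            bound_site=np.array([-1]))
        topo = Topology(n_mon=2, n_mol=1, binding_sites=[0, 1])
        return state, topo

    def test_capture_within_radius(self, params):
        state, topo = self._setup([3.0, 2, 2], params)  # 1 sigma from site 0
        update_bindings(state, topo, params)
        assert state.bound_site[0] == 0

    def test_nearest_site_wins_and_tie_breaks_low(self, params):
        # molecule at 1.5 sigma from site 0, 2.5 from site 1 -> site 0
        state, topo = self._setup([3.5, 2, 2], params)
        update_bindings(state, topo, params)
        assert state.bound_site[0] == 0
        # exact midpoint: equidistant -> lower site index
        state, topo = self._setup([4.0, 2, 2], params)
        update_bindings(state, topo, params)
        assert state.bound_site[0] == 0

    def test_release_beyond_threshold(self, params):
        state, topo = self._setup([3.0, 2, 2], params)
        update_bindings(state, topo, params)
        assert state.bound_site[0] == 0
        state.positions[2] = [2.0, 2 + 3.0, 2]  # 3 sigma away from both sites
        update_bindings(state, topo, params)
        assert state.bound_site[0] == -1

    def test_one_site_per_molecule_many_molecules_per_site(self, params):
        pos = np.array([[5.0, 5, 5], [5.8, 5, 5], [5.0, 5.8, 5]])
        state = SystemState(pos, np.zeros_like(pos), box=params.box_side,
                            bound_site=np.array([-1, -1]))
        topo = Topology(n_mon=1, n_mol=2, binding_sites=[0])
        update_bindings(state, topo, params)
        assert list(state.bound_site) == [0, 0]


class TestInitialConfiguration:
    def test_bond_lengths_and_finite_energy(self):
        params = SimulationParameters.from_density(60, 0.05)
        topo = make_topology(n_mon=30, n_mol=30, n_c=5, rng=2)
        state = place_initial_configuration(params, topo, 4)
        bonds = np.linalg.norm(np.diff(state.positions[:30], axis=0), axis=1)
        assert np.all(bonds >= 0.5) and np.all(bonds < params.R0)
        assert np.isfinite(ff.total_energy(state, topo, params))

    def test_two_monomer_bond_within_fene_range(self):
        params = SimulationParameters.from_density(2, 0.001)
        topo = Topology(n_mon=2)
        state = place_initial_configuration(params, topo, 0)
        d = np.linalg.norm(state.positions[1] - state.positions[0])
        assert 0.5 <= d < params.R0

    def test_velocity_variance(self):
        params = SimulationParameters.from_density(10_002, 0.01)
        topo = Topology(n_mon=2, n_mol=10_000)
        state = place_initial_configuration(params, topo, 9)
        var = np.var(state.velocities, axis=0)
        np.testing.assert_allclose(var, params.kT / params.mass, rtol=0.05)
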