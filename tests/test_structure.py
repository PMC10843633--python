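"""Structural analysis: R_g, the PSD region, RDFs, pore sizes, scaling fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rclpsd.fixtures import make_ideal_gas
from rclpsd.structure import (
    PSDRegion,
    fit_power_law_offset,
    gyration_radius,
    pore_size_at,
    pore_size_distribution,
    pore_size_grid_oracle,
    radial_distribution,
)


class TestGyrationRadius:
    def test_examples(self):
        assert gyration_radius(np.array([[0.0, 0, 0], [3.0, 0, 0]])) == pytest.approx(1.5)
        assert gyration_radius(np.array([[2.0, 1, 7]])) == 0.0
        square = np.array([[0.5, 0.5, 0], [0.5, -0.5, 0], [-0.5, 0.5, 0], [-0.5, -0.5, 0]])
        assert gyration_radius(square) == pytest.approx(1 / np.sqrt(2))

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(40, 3))
        rg0 = gyration_radius(pts)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert gyration_radius(pts @ q.T + np.array([5.0, -3.0, 11.0])) == pytest.approx(rg0)

    def test_discontiguous_chain_rejected(self):
        chain = np.array([[0.0, 0, 0], [1.0, 0, 0], [9.5, 0, 0]])  # wrapped-looking jump
        with pytest.raises(ValueError, match="unwrap"):
            gyration_radius(chain, max_bond=2.0)


class TestPSDRegion:
    def test_membership_and_depth(self):
        om = PSDRegion(radius=3.0)
        assert om.depth(np.zeros(3)) == pytest.approx(3.0)
        assert om.depth(np.array([3.0, 0, 0])) == pytest.approx(0.0)
        assert om.depth(np.array([6.0, 0, 0])) == pytest.approx(-3.0)
        assert om.contains(np.array([[0.0, 0, 0], [6.0, 0, 0]])).tolist() == [True, False]

    def test_moving_center(self):
        om = PSDRegion(radius=2.0)
        assert om.contains(np.array([5.0, 5, 5]), center=np.array([5.5, 5, 5]))


class TestRadialDistribution:
    def test_uniform_gas_is_flat(self):
        box = 20.0
        rng = np.random.default_rng(3)
        frames = np.stack([make_ideal_gas(10_000, box, rng=rng)[0] for _ in range(150)])
        prof = radial_distribution(
            frames, box, kind="com",
            centers=np.tile([[box / 2] * 3], (150, 1)), bin_width=0.5,
        )
        sel = (prof.bin_centers > 2.0) & (prof.bin_centers < box / 4)
        assert np.all(np.abs(prof.values[sel] - 1.0) < 0.05)

    def test_uniform_gas_pair_correlation_flat(self):
        box = 12.0
        pos, _ = make_ideal_gas(3000, box, rng=4)
        prof = radial_distribution(pos[None], box, kind="pair", positions_b=pos[None],
                                   bin_width=0.25)
        sel = (prof.bin_centers > 1.5) & (prof.bin_centers < box / 4)
        assert np.abs(np.mean(prof.values[sel]) - 1.0) < 0.02
        assert np.all(np.abs(prof.values[sel] - 1.0) < 0.1)

    def test_excluded_core_gives_zero(self, rng):
        # all particles outside radius 5 from the reference center
        box = 30.0
        u = rng.normal(size=(2000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos = box / 2 + u * rng.uniform(5.0, 8.0, size=(2000, 1))
        prof = radial_distribution(pos[None], box, kind="com",
                                   centers=np.array([[box / 2] * 3]), bin_width=0.2)
        inner = prof.bin_centers < 4.8
        assert np.all(prof.values[inner] == 0.0)

    def test_two_fixed_particles_single_bin(self):
        box = 10.0
        d = 2.34
        pos = np.array([[[1.0, 1, 1], [1.0 + d, 1, 1]]])
        prof = radial_distribution(pos, box, kind="pair", positions_b=pos, bin_width=0.1)
        nz = np.nonzero(prof.counts)[0]
        assert len(nz) == 1
        lo, hi = prof.bin_edges[nz[0]], prof.bin_edges[nz[0] + 1]
        assert lo <= d < hi

    def test_single_particle_pair_rdf_rejected(self):
        pos = np.zeros((1, 1, 3))
        with pytest.raises(ValueError):
            radial_distribution(pos, 10.0, kind="pair", positions_b=pos)


class TestPoreSize:
    def test_empty_region_gives_region_radius(self):
        psd = pore_size_distribution(np.empty((0, 3)), region_radius=2.5, n_probes=50, rng=1)
        np.testing.assert_allclose(psd.radii, 2.5)
        assert psd.mesh_size == pytest.approx(2.5)

    @pytest.mark.parametrize("n_mon", [1, 3, 5])
    def test_matches_grid_oracle(self, n_mon, rng):
        """Optimization-based pore size equals exhaustive lattice search."""
        R = 2.0
        local = np.random.default_rng(n_mon)
        mon = local.uniform(-1.2, 1.2, size=(n_mon, 3))
        step = 0.05
        for _ in range(6):
            u = local.normal(size=3)
            p = u / np.linalg.norm(u) * local.uniform(0, 0.9 * R)
            s_opt = pore_size_at(p, mon, R, exclusion=0.5)
            s_grid = pore_size_grid_oracle(p, mon, R, exclusion=0.5, grid_step=step)
            # lattice search underestimates by at most the grid diagonal
            assert s_opt >= s_grid - 1e-9
            assert s_opt - s_grid <= np.sqrt(3) * step + 1e-9

    def test_obstacle_monotonicity(self, rng):
        """Adding a monomer can only shrink (never grow) any pore."""
        R = 2.0
        mon = rng.uniform(-1.0, 1.0, size=(3, 3))
        extra = np.vstack([mon, rng.uniform(-1.0, 1.0, size=(1, 3))])
        for _ in range(5):
            p = rng.uniform(-0.8, 0.8, size=3)
            if np.linalg.norm(p) > R:
                continue
            assert pore_size_at(p, extra, R) <= pore_size_at(p, mon, R) + 1e-7

    def test_probe_outside_region_rejected(self):
        with pytest.raises(ValueError):
            pore_size_at(np.array([5.0, 0, 0]), np.zeros((1, 3)), region_radius=2.0)


class TestScalingFit:
    def test_exact_recovery_noiseless(self):
        x = np.arange(10.0, 101.0, 5.0)
        y = 2.0 * x**-0.5 + 1.0
        fit = fit_power_law_offset(x, y, form="decay")
        assert fit.amplitude == pytest.approx(2.0, abs=1e-6)
        assert fit.exponent == pytest.approx(0.5, abs=1e-6)
        assert fit.offset == pytest.approx(1.0, abs=1e-6)

    def test_growth_form(self):
        x = np.arange(4.0, 40.0, 2.0)
        y = 0.3 * x**1.7 + 5.0
        fit = fit_power_law_offset(x, y, form="growth")
        assert fit.exponent == pytest.approx(1.7, abs=1e-6)
        assert fit.predict(np.array([10.0]))[0] == pytest.approx(0.3 * 10**1.7 + 5.0)

    def test_constant_input_flagged(self):
        x = np.arange(1.0, 9.0)
        fit = fit_power_law_offset(x, np.full(8, 3.3), form="decay")
        assert not fit.exponent_identifiable
        assert fit.offset == pytest.approx(3.3)

    def test_noisy_recovery_coverage(self):
        """With 5% noise the true exponent lies within 3 SE in >= 95% of replicates."""
        rng = np.random.default_rng(7)
        x = np.linspace(10, 200, 20)
        k, e, c = 5.0, 0.7, 2.0
        truth = k * x**-e + c
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = truth * (1 + 0.05 * rng.normal(size=len(x)))
            fit = fit_power_law_offset(x, y, form="decay")
            if abs(fit.exponent - e) <= 3 * fit.stderr[1]:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law_offset([1, 2, 3], [1, 2, 3], form="decay")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_gyration_radius_nonnegative_and_translation_free(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(rng.integers(1, 30), 3)) * rng.uniform(0.1, 10)
    rg = gyration_radius(pts)
    assert rg >= 0
    assert gyration_radius(pts + rng.normal(size=3) * 100) == pytest.approx(rg, rel=1e-9, abs=1e-9)
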