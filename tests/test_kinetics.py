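"""Kinetic observables: episodes, binding, local density, escape, MSD, alpha."""

import numpy as np
import pytest

from rclpsd.fixtures import make_brownian_tracks, make_ou_well_tracks, ou_msd
from rclpsd.kinetics import (
    anomalous_exponent,
    binding_times,
    conditional_msd,
    escape_times,
    local_density_at_sites,
    residence_and_penetration,
)


class TestResidenceEpisodes:
    def test_scripted_single_episode(self):
        """Track entering at t=10, exiting at t=25, min radius 0.8 R."""
        R = 5.0
        times = np.arange(40.0)
        radii = np.full(40, 1.2 * R)
        radii[10:25] = np.linspace(0.95, 0.8, 15) * R
        es = residence_and_penetration(radii, times, R)
        assert len(es.episodes) == 1
        ep = es.episodes[0]
        assert not ep.censored
        assert ep.duration == pytest.approx(15.0)
        assert ep.max_depth == pytest.approx(0.2 * R)

    def test_never_entering(self):
        times = np.arange(20.0)
        es = residence_and_penetration(np.full(20, 9.0), times, 5.0)
        assert es.episodes == []

    def test_grazing_touch_is_no_episode(self):
        # touching the boundary exactly (r = R) is not a crossing (inside is r < R)
        R = 5.0
        radii = np.array([6.0, 5.5, 5.0, 5.5, 6.0])
        es = residence_and_penetration(radii, np.arange(5.0), R)
        assert es.episodes == []

    def test_censoring_never_alters_completed_episodes(self):
        rng = np.random.default_rng(0)
        radii = 5.0 + np.cumsum(rng.normal(0, 0.6, size=300))
        times = np.arange(300.0)
        full = residence_and_penetration(radii, times, 5.0)
        short = residence_and_penetration(radii[:200], times[:200], 5.0)
        done_full = [(e.entry_time, e.exit_time) for e in full.completed() if e.exit_time <= 200]
        done_short = [(e.entry_time, e.exit_time) for e in short.completed()]
        # truncation may censor the last visit but never changes earlier ones
        assert done_short == done_full[: len(done_short)]
        assert len(done_full) - len(done_short) <= 1

    def test_brownian_penetration_matches_independent_oracle(self):
        """Mean L_in of Brownian visits vs a plain-loop reference implementation."""
        R = 2.0
        tracks, _ = make_brownian_tracks(40, D=1.0, dt=0.01, n_steps=2000, rng=11,
                                         sphere_radius=3.0, start="uniform")
        times = np.arange(tracks.shape[1]) * 0.01
        radii = np.linalg.norm(tracks, axis=-1)
        depths = []
        for m in range(len(tracks)):
            es = residence_and_penetration(radii[m], times, R)
            depths.extend(e.max_depth for e in es.completed())
        # independent oracle: naive per-sample scan
        ref = []
        for m in range(len(tracks)):
            r = radii[m]
            inside = r < R
            k = 0
            while k < len(r):
                if inside[k]:
                    j = k
                    while j < len(r) and inside[j]:
                        j += 1
                    if k > 0 and j < len(r):
                        ref.append(R - r[k:j].min())
                    k = j
                else:
                    k += 1
        assert len(depths) == len(ref)
        assert np.mean(depths) == pytest.approx(np.mean(ref), rel=1e-12)


class TestBindingTimes:
    def test_interval_lengths(self):
        reg = np.full((20, 1), -1)
        reg[5:15, 0] = 3  # bound frames 5..14
        bi = binding_times(reg, np.arange(20.0))
        assert bi.durations.tolist() == [10.0]
        assert not bi.censored[0]

    def test_alternating_frames(self):
        reg = np.full((10, 1), -1)
        reg[1::2, 0] = 0
        bi = binding_times(reg, np.arange(10.0))
        done = bi.completed()
        assert np.all(done == 1.0)

    def test_always_bound_is_censored(self):
        reg = np.zeros((50, 1), dtype=int)
        bi = binding_times(reg, np.arange(50.0))
        assert len(bi.durations) == 1
        assert bi.censored[0]
        assert bi.durations[0] == pytest.approx(50.0)
        assert np.isnan(bi.mean())


class TestLocalDensity:
    def test_uniform_molecules_ratio_one(self):
        box = 10.0
        rng = np.random.default_rng(5)
        mols = rng.uniform(0, box, size=(40, 2000, 3))
        sites = rng.uniform(0, box, size=(40, 4, 3))
        ratio = local_density_at_sites(mols, sites, box, probe_radius=1.5)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_empty_neighbourhood(self):
        box = 10.0
        mols = np.full((1, 5, 3), 8.0)
        sites = np.array([[[2.0, 2, 2]]])
        assert local_density_at_sites(mols, sites, box, probe_radius=1.0) == 0.0

    def test_all_packed_at_one_site(self):
        box = 10.0
        n = 20
        mols = np.full((1, n, 3), 5.0) + np.random.default_rng(1).normal(0, 0.05, (1, n, 3))
        sites = np.array([[[5.0, 5, 5]]])
        probe = 0.5
        ratio = local_density_at_sites(mols, sites, box, probe_radius=probe)
        v_probe = 4 / 3 * np.pi * probe**3
        assert ratio == pytest.approx(box**3 / v_probe, rel=1e-9)


class TestEscapeTimes:
    def test_brownian_from_center_closed_form(self):
        """<tau_e> from the center of a sphere R equals R^2/(6D) within 5%."""
        R, D, dt = 1.0, 1.0, 2e-4
        tracks, spec = make_brownian_tracks(1000, D=D, dt=dt, n_steps=8000, rng=21,
                                            sphere_radius=R)
        radii = np.linalg.norm(tracks, axis=-1)
        et = escape_times(radii, np.arange(tracks.shape[1]) * dt, R)
        assert et.censored.sum() == 0
        assert et.mean() == pytest.approx(spec.ground_truth["mean_escape_time"], rel=0.05)

    def test_start_outside_rejected(self):
        radii = np.array([[2.0, 1.0, 0.5]])
        with pytest.raises(ValueError):
            escape_times(radii, np.arange(3.0), 1.0)

    def test_deterministic_outward_drift(self):
        v, R = 0.5, 3.0
        times = np.arange(0, 20, 0.1)
        radii = (v * times)[None, :]
        et = escape_times(radii, times, R)
        # R/v up to frame resolution (crossing dated at the frame after)
        assert et.times[0] == pytest.approx(R / v, abs=0.100001)

    def test_all_censored_reports_lower_bound(self):
        radii = np.zeros((3, 10))
        et = escape_times(radii, np.arange(10.0), 5.0)
        assert et.all_censored
        assert np.isnan(et.mean())
        assert et.lower_bound() == pytest.approx(9.0)


class TestConditionalMSD:
    def test_free_brownian_all_annuli(self):
        D, dt = 1.0, 0.01
        tracks, _ = make_brownian_tracks(800, D=D, dt=dt, n_steps=400, rng=31,
                                         sphere_radius=2.0, start="uniform")
        times = np.arange(tracks.shape[1]) * dt
        cm = conditional_msd(tracks, times, dr=0.5, lags=np.arange(1, 11), r_max=2.0)
        for a in range(cm.msd.shape[0]):
            ok = cm.counts[a] > 2000
            if ok.sum() < 3:
                continue
            np.testing.assert_allclose(cm.msd[a, ok], 6 * D * cm.lags[ok], rtol=0.05)

    def test_immobile_particles(self):
        tracks = np.ones((5, 50, 3))
        cm = conditional_msd(tracks, np.arange(50.0), dr=1.0)
        assert np.nanmax(cm.msd) == 0.0

    def test_empty_annulus_is_nan(self):
        tracks = np.ones((2, 30, 3))  # radius sqrt(3) only
        cm = conditional_msd(tracks, np.arange(30.0), dr=0.5, r_max=5.0)
        assert np.all(np.isnan(cm.msd[0]))  # nothing near the origin

    def test_ou_plateau_matches_closed_form(self):
        lam, D, dt = 2.0, 1.0, 0.05
        tracks, _ = make_ou_well_tracks(400, lam, D, dt, 400, rng=41)
        times = np.arange(tracks.shape[1]) * dt
        lags = np.arange(1, 61)
        cm = conditional_msd(tracks, times, dr=10.0, lags=lags)  # one annulus
        expected = ou_msd(cm.lags, lam, D)
        sel = cm.lags > 2.0 / lam  # plateau region
        np.testing.assert_allclose(cm.msd[0, sel], expected[sel], rtol=0.05)


class TestAnomalousExponent:
    def _single_annulus(self, msd_fn, lags):
        from rclpsd.kinetics import ConditionalMSD

        lagt = lags.astype(float)
        return ConditionalMSD(
            annulus_edges=np.array([0.0, 1.0]),
            lags=lagt,
            msd=msd_fn(lagt)[None, :],
            counts=np.full((1, len(lags)), 1000),
        )

    def test_linear_msd_gives_alpha_one(self):
        cm = self._single_annulus(lambda t: 6 * 2.0 * t, np.arange(1, 20))
        spec = anomalous_exponent(cm, window=(1, 19))
        assert spec.alpha[0] == pytest.approx(1.0, abs=1e-12)
        assert spec.d_inf[0] == pytest.approx(12.0)

    def test_subdiffusive_msd(self):
        cm = self._single_annulus(lambda t: 3.0 * t**0.5, np.arange(1, 20))
        spec = anomalous_exponent(cm, window=(1, 19))
        assert spec.alpha[0] == pytest.approx(0.5, abs=1e-12)

    def test_ou_window_slope_matches_closed_form(self):
        lam, D = 1.0, 1.0
        lags = np.arange(1, 30)
        cm = self._single_annulus(lambda t: ou_msd(t, lam, D), lags)
        spec = anomalous_exponent(cm, window=(1, 10))
        # the same least-squares slope on the analytic curve
        sel = (lags >= 1) & (lags <= 10)
        ref = np.polyfit(np.log(lags[sel]), np.log(ou_msd(lags[sel], lam, D)), 1)[0]
        assert spec.alpha[0] == pytest.approx(ref, rel=1e-9)
        assert spec.alpha[0] < 1.0

    def test_insufficient_window_raises(self):
        cm = self._single_annulus(lambda t: t, np.arange(1, 20))
        with pytest.raises(ValueError):
            anomalous_exponent(cm, window=(50, 60))
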