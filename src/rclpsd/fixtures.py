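"""Synthetic fixtures with analytic ground truth.

Each generator returns its data plus a :class:`FixtureSpec` recording the
closed-form values the fixture encodes (uniform g(r) = 1, MSD = 6 D tau,
OU drift -lambda x and stationary variance D/lambda, scripted episode
times), so every analysis operation can be validated without running the
polymer simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class FixtureSpec:
    kind: str
    parameters: dict
    ground_truth: dict


def make_ideal_gas(
    n: int, box: float, rng: np.random.Generator | int = 0
) -> tuple[np.ndarray, FixtureSpec]:
    """Uniform points in a periodic cube; g(r) = 1 everywhere."""
    if n < 1:
        raise ValueError("need n >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pos = rng.uniform(0.0, box, size=(n, 3))
    spec = FixtureSpec(
        kind="ideal_gas",
        parameters={"n": n, "box": box},
        ground_truth={"g": 1.0, "density": n / box**3},
    )
    return pos, spec


def make_brownian_tracks(
    n_tracks: int,
    D: float,
    dt: float,
    n_steps: int,
    rng: np.random.Generator | int = 0,
    sphere_radius: float | None = None,
    start: str = "origin",
) -> tuple[np.ndarray, FixtureSpec]:
    """Free Brownian tracks: Gaussian increments of variance 2 D dt per axis.

    With ``sphere_radius`` the ground truth records the mean first exit time
    R^2/(6 D) from the center of a sphere of that radius (the tracks
    themselves are not stopped; escape detection is the analysis job).
    """
    if D <= 0 or dt <= 0:
        raise ValueError("D and dt must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_tracks, n_steps, 3))
    x = np.concatenate(
        [np.zeros((n_tracks, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    if start == "uniform" and sphere_radius is not None:
        u = rng.normal(size=(n_tracks, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r0 = sphere_radius * rng.random(n_tracks) ** (1.0 / 3.0)
        x = x + (u * r0[:, None])[:, None, :]
    gt = {"msd_slope": 6.0 * D, "alpha": 1.0, "drift": 0.0}
    if sphere_radius is not None:
        gt["mean_escape_time"] = sphere_radius**2 / (6.0 * D)
    spec = FixtureSpec(
        kind="brownian",
        parameters={"n_tracks": n_tracks, "D": D, "dt": dt, "n_steps": n_steps,
                    "sphere_radius": sphere_radius},
        ground_truth=gt,
    )
    return x, spec


def make_ou_well_tracks(
    n_tracks: int,
    lam: float,
    D: float,
    dt: float,
    n_steps: int,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, FixtureSpec]:
    """Ornstein-Uhlenbeck tracks dX = -lam X dt + sqrt(2D) dW, per component.

    Uses the exact discretization (mean e^{-lam dt} x, variance
    (D/lam)(1 - e^{-2 lam dt})), started from the stationary law, so the
    recorded ground truth (drift slope -lam, stationary variance D/lam,
    well coefficient A = R_g^2 lam / 2) is bias-free at any dt.
    """
    if lam <= 0 or D <= 0 or dt <= 0:
        raise ValueError("lam, D and dt must be positive")
    if dt >= 1.0 / lam:
        warnings.warn("dt >= 1/lam: drift estimated at this sampling interval is biased")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    decay = np.exp(-lam * dt)
    sd_step = np.sqrt(D / lam * (1.0 - decay**2))
    sd_stat = np.sqrt(D / lam)
    x = np.empty((n_tracks, n_steps + 1, 3))
    x[:, 0] = rng.normal(0.0, sd_stat, size=(n_tracks, 3))
    noise = rng.normal(0.0, sd_step, size=(n_tracks, n_steps, 3))
    for k in range(n_steps):
        x[:, k + 1] = decay * x[:, k] + noise[:, k]
    spec = FixtureSpec(
        kind="ou_well",
        parameters={"n_tracks": n_tracks, "lam": lam, "D": D, "dt": dt, "n_steps": n_steps},
        ground_truth={
            "drift_slope": -lam,
            "stationary_variance": D / lam,
            "msd_plateau": 6.0 * D / lam,
            "well_A_per_rg2": lam / 2.0,  # A = R_g^2 lam / 2
        },
    )
    return x, spec


def ou_msd(tau: np.ndarray, lam: float, D: float) -> np.ndarray:
    """Closed-form 3-D OU mean square displacement 6(D/lam)(1 - e^{-lam tau})."""
    return 6.0 * D / lam * (1.0 - np.exp(-lam * np.asarray(tau, dtype=float)))


def make_scripted_track(
    waypoints: np.ndarray, dt: float, substeps: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear track through waypoints sampled every ``dt``.

    With ``substeps`` > 1 each segment is subdivided evenly.  Returns
    (positions, times).
    """
    wp = np.asarray(waypoints, dtype=float).reshape(-1, 3)
    if len(wp) < 2:
        raise ValueError("need at least 2 waypoints")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    segs = []
    for a, b in zip(wp[:-1], wp[1:]):
        frac = np.linspace(0.0, 1.0, substeps + 1)[:-1, None]
        segs.append(a + frac * (b - a))
    pos = np.vstack(segs + [wp[-1:]])
    times = np.arange(len(pos)) * dt / substeps
    return pos, times
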