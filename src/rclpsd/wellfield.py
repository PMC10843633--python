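"""Drift-field reconstruction and potential-well diagnostics.

From an ensemble of trajectories the local drift a(x) is estimated on a
cubic lattice as the per-bin mean displacement per unit time.  A truncated
parabolic (elliptic) well centered at the origin with semi-axes R_g implies
the radial-linear drift a(x) = -(2A/R_g^2) x; the attraction coefficient A
is recovered by least squares and the parabolic index S in [0, 1] measures
how close the empirical field is to such a well (S = 0: perfect well,
S -> 1: isotropic random field, e.g. pure diffusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DriftGrid:
    """Binned drift field: bin centers x_k, drift vectors a(x_k), counts N_k."""

    centers: np.ndarray  # (M, 3)
    drift: np.ndarray  # (M, 3)
    counts: np.ndarray  # (M,)
    dx: float
    dt: float

    def restrict(self, r_max: float) -> "DriftGrid":
        sel = np.linalg.norm(self.centers, axis=1) <= r_max
        return DriftGrid(self.centers[sel], self.drift[sel], self.counts[sel], self.dx, self.dt)


@dataclass
class WellFit:
    """Truncated-parabola fit: attraction coefficient A and parabolic index S."""

    A: float
    attracting: bool
    S: float
    semi_axis: float
    n_bins: int


def estimate_drift(
    tracks: np.ndarray,
    dt: float,
    dx: float,
    min_count: int = 20,
    extent: float | None = None,
    box: float | None = None,
) -> DriftGrid:
    """Per-bin mean displacement per unit time over all trajectory points.

    ``tracks`` is (n_traj, n_frames, 3) sampled at fixed ``dt`` in the frame
    whose origin is the candidate well center.  Bins with fewer than
    ``min_count`` points are dropped.  With ``box`` set, displacements are
    folded by minimum image (for tracks wrapped into a periodic box).
    """
    x = np.asarray(tracks, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if dx <= 0 or dt <= 0:
        raise ValueError("dx and dt must be positive")
    start = x[:, :-1].reshape(-1, 3)
    d = (x[:, 1:] - x[:, :-1]).reshape(-1, 3)
    if box is not None:
        d -= box * np.round(d / box)
    disp = d / dt
    if extent is None:
        extent = float(np.max(np.abs(start))) + dx
    nb = max(1, int(np.ceil(2 * extent / dx)))
    sums, counts = bin_drift_samples(start, disp, dx, nb)
    return grid_from_sums(sums, counts, dx, dt, min_count)


def bin_drift_samples(start: np.ndarray, disp: np.ndarray, dx: float, nb: int):
    """Accumulate displacement-rate sums/counts on an origin-centered cubic
    lattice of nb^3 bins of width dx (samples outside are dropped)."""
    origin = -0.5 * nb * dx
    idx = np.floor((start - origin) / dx).astype(int)
    ok = np.all((idx >= 0) & (idx < nb), axis=1)
    idx = idx[ok]
    disp = disp[ok]
    flat = (idx[:, 0] * nb + idx[:, 1]) * nb + idx[:, 2]
    counts = np.bincount(flat, minlength=nb**3)
    sums = np.zeros((nb**3, 3))
    for d in range(3):
        sums[:, d] = np.bincount(flat, weights=disp[:, d], minlength=nb**3)
    return sums, counts


def grid_from_sums(sums, counts, dx: float, dt: float, min_count: int) -> DriftGrid:
    nb = round(len(counts) ** (1 / 3))
    keep = counts >= min_count
    if not np.any(keep):
        raise ValueError("no drift bin reached min_count points")
    kk = np.nonzero(keep)[0]
    ii = np.stack(np.unravel_index(kk, (nb, nb, nb)), axis=1)
    centers = -0.5 * nb * dx + (ii + 0.5) * dx
    drift = sums[kk] / counts[kk, None]
    return DriftGrid(centers=centers, drift=drift, counts=counts[kk], dx=dx, dt=dt)


def fit_parabolic_A(grid: DriftGrid, r_g: float) -> WellFit:
    """Least-squares attraction coefficient of a parabolic well with semi-axes R_g.

    A = (R_g^2 / 2) |sum_k a(x_k).x_k| / sum_k |x_k|^2, over bins with
    |x_k| <= R_g (the well is truncated at its boundary).  ``attracting``
    records the drift orientation (True: inward).  The parabolic index of
    the same restricted grid is included.
    """
    g = grid.restrict(r_g)
    if g.centers.shape[0] < 1:
        raise ValueError("no populated bins inside the well")
    sx2 = float(np.sum(g.centers**2))
    if sx2 == 0.0:
        raise ValueError("all bin coordinates are zero; A undefined")
    sax = float(np.sum(g.drift * g.centers))
    A = 0.5 * r_g**2 * abs(sax) / sx2
    try:
        S = parabolic_index(g)
    except ValueError:  # zero drift everywhere: A = 0, S undefined
        S = np.nan
    return WellFit(
        A=A,
        attracting=sax < 0,
        S=S,
        semi_axis=r_g,
        n_bins=g.centers.shape[0],
    )


def parabolic_index(grid: DriftGrid) -> float:
    """Quality-of-well index S = 1 - (sum a.x)^2 / (sum |x|^2 sum |a|^2).

    By Cauchy-Schwarz S lies in [0, 1]; S = 0 iff a(x) is exactly
    proportional to -x (radial linear drift), S -> 1 for an uncorrelated
    random drift field.
    """
    if grid.centers.shape[0] < 2:
        raise ValueError("need at least 2 populated bins")
    sax = float(np.sum(grid.drift * grid.centers))
    sx2 = float(np.sum(grid.centers**2))
    sa2 = float(np.sum(grid.drift**2))
    if sa2 == 0.0:
        raise ValueError("zero drift everywhere; S undefined")
    s = 1.0 - sax**2 / (sx2 * sa2)
    return float(min(max(s, 0.0), 1.0))
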