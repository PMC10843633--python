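"""Structural observables: gyration radius, the PSD region, radial
distribution functions, pore-size distribution / mesh size, and
power-law-with-offset scaling fits.

The phase-separated domain (PSD) is the ball Omega of radius <R_g> around
the instantaneous polymer center of mass; all radial statistics are taken
relative to that (moving) center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize

from .trajectory import TrajectoryEnsemble


# ----------------------------------------------------------- gyration radius


def gyration_radius(positions: np.ndarray, max_bond: float | None = None) -> float | np.ndarray:
    """Root-mean-square distance of points from their center of mass.

    ``positions`` is (N, 3) or (n_frames, N, 3) (unwrapped).  When
    ``max_bond`` is given the input is treated as a chain and consecutive
    distances above it raise (wrapped coordinates must be unwrapped first).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
        squeeze = True
    else:
        squeeze = False
    if pos.shape[-1] != 3 or pos.shape[-2] < 1:
        raise ValueError("positions must be (..., N>=1, 3)")
    if max_bond is not None and pos.shape[-2] > 1:
        bonds = np.linalg.norm(np.diff(pos, axis=-2), axis=-1)
        if np.any(bonds > max_bond):
            raise ValueError(
                "consecutive monomer distance exceeds max_bond: chain looks "
                "wrapped/discontiguous, unwrap before computing R_g"
            )
    cm = pos.mean(axis=-2, keepdims=True)
    rg = np.sqrt(np.mean(np.sum((pos - cm) ** 2, axis=-1), axis=-1))
    return float(rg[0]) if squeeze else rg


def mean_gyration_radius(ens: TrajectoryEnsemble) -> float:
    """Frame-averaged R_g of the polymer in one run."""
    return float(np.mean(gyration_radius(ens.monomer_frames())))


# ----------------------------------------------------------------- PSD region


@dataclass(frozen=True)
class PSDRegion:
    """The ball Omega of radius <R_g> around the instantaneous chain CM.

    ``depth`` is the signed distance below the boundary,
    ``<R_g> - |r - r_CM|``: positive inside, zero on the boundary.
    """

    radius: float

    def depth(self, positions: np.ndarray, center: np.ndarray = None) -> np.ndarray:
        pos = np.asarray(positions, dtype=float)
        if center is not None:
            pos = pos - np.asarray(center, dtype=float)
        return self.radius - np.linalg.norm(pos, axis=-1)

    def contains(self, positions: np.ndarray, center: np.ndarray = None) -> np.ndarray:
        return self.depth(positions, center) >= 0.0

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3


def psd_region(ens: TrajectoryEnsemble) -> PSDRegion:
    """Omega for one run: radius = frame-averaged R_g of this realization."""
    return PSDRegion(radius=mean_gyration_radius(ens))


def molecule_coords_rel_cm(ens: TrajectoryEnsemble) -> np.ndarray:
    """Unwrapped molecule positions relative to the instantaneous chain CM,
    folded by minimum image into the primary box, shape (F, n_mol, 3)."""
    rel = ens.molecule_frames() - ens.center_of_mass()[:, None, :]
    return rel - ens.box * np.round(rel / ens.box)


# ---------------------------------------------------- radial distributions


@dataclass
class RadialProfile:
    """Shell-histogram estimate of a radial distribution function g(r)."""

    bin_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    kind: str
    n_frames: int
    volume: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean_in(self, r_lo: float, r_hi: float) -> float:
        """Shell-volume-weighted mean of g over [r_lo, r_hi] (occupancy ratio)."""
        c = self.bin_centers
        sel = (c >= r_lo) & (c < r_hi)
        if not np.any(sel):
            raise ValueError("no bins in requested range")
        w = np.diff(self.bin_edges**3)[sel]
        return float(np.sum(self.values[sel] * w) / np.sum(w))


def _shell_volumes(edges: np.ndarray) -> np.ndarray:
    return 4.0 / 3.0 * np.pi * np.diff(edges**3)


def radial_distribution(
    positions: np.ndarray,
    box: float,
    kind: str = "com",
    centers: np.ndarray | None = None,
    positions_b: np.ndarray | None = None,
    bin_width: float = 0.1,
    r_max: float | None = None,
) -> RadialProfile:
    """Radial distribution normalized so a uniform ideal system gives 1.

    kind='com': g(r) of ``positions`` (F, N, 3) about per-frame ``centers``
    (F, 3), the paper's g_mol / g_mon.  kind='pair': pair correlation between
    ``positions`` and ``positions_b`` (minimum image; same array for the
    same-species functions).  Normalization is by exact shell volumes, which
    converges to the 1/(4 pi r^2 dr) convention as the bins shrink.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    if pos.shape[0] == 0 or pos.shape[1] == 0:
        raise ValueError("need at least one frame with at least one particle")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if r_max is None:
        r_max = box / 2.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    V = box**3
    n_frames = pos.shape[0]
    shells = _shell_volumes(edges)

    if kind == "com":
        if centers is None:
            raise ValueError("kind='com' requires per-frame centers")
        centers = np.asarray(centers, dtype=float).reshape(n_frames, 3)
        rel = pos - centers[:, None, :]
        rel -= box * np.round(rel / box)
        r = np.linalg.norm(rel, axis=-1).ravel()
        counts, _ = np.histogram(r, bins=edges)
        n_per_frame = pos.shape[1]
        expected = n_per_frame * shells / V
        values = counts / (n_frames * expected)
    elif kind == "pair":
        if positions_b is None:
            raise ValueError("kind='pair' requires positions_b")
        pb = np.asarray(positions_b, dtype=float)
        if pb.ndim == 2:
            pb = pb[None]
        same = pos.shape == pb.shape and np.array_equal(pos, pb)
        counts = np.zeros(len(edges) - 1, dtype=float)
        for f in range(n_frames):
            d = pos[f][:, None, :] - pb[f][None, :, :]
            d -= box * np.round(d / box)
            r = np.linalg.norm(d, axis=-1)
            rr = r[np.triu_indices(r.shape[0], k=1)] if same else r.ravel()
            c, _ = np.histogram(rr, bins=edges)
            counts += c
        na, nb = pos.shape[1], pb.shape[1]
        n_pairs = na * (na - 1) / 2.0 if same else na * nb
        if n_pairs == 0:
            raise ValueError("pair RDF undefined for fewer than two particles")
        expected = n_pairs * shells / V
        values = counts / (n_frames * expected)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return RadialProfile(
        bin_edges=edges,
        values=values,
        counts=counts.astype(np.int64) if kind == "com" else counts,
        kind=kind,
        n_frames=n_frames,
        volume=V,
    )


# ----------------------------------------------------- pore-size distribution


@dataclass
class PoreSizeDistribution:
    """Samples of the pore-size function inside Omega and their mean (mesh size).

    The pore size s(p) of a probe point p is the radius of the largest
    sphere that contains p, lies inside Omega, and avoids every monomer
    hard core (radius sigma/2) — the covering pore-size function of void
    statistics.
    """

    radii: np.ndarray

    @property
    def mesh_size(self) -> float:
        return float(np.mean(self.radii)) if len(self.radii) else 0.0

    def density(self, bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
        hist, edges = np.histogram(self.radii, bins=bins, density=True)
        return 0.5 * (edges[:-1] + edges[1:]), hist


def pore_size_at(
    probe: np.ndarray,
    monomers: np.ndarray,
    region_radius: float,
    center: np.ndarray = None,
    exclusion: float = 0.5,
) -> float:
    """Largest-covering-sphere radius for one probe point.

    Solves  max r  over sphere centers c subject to
    |c - m_i| >= r + exclusion (void of monomer hard cores),
    |c - center| <= R_Omega - r (sphere inside Omega),
    |c - p| <= r (sphere covers the probe),
    with SLSQP from multiple starts.  Returns 0 for an inadmissible probe.
    """
    p = np.asarray(probe, dtype=float)
    mon = np.asarray(monomers, dtype=float).reshape(-1, 3)
    c0 = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    R = float(region_radius)

    def gap(c):
        """Largest admissible radius of a sphere centered at c."""
        g = R - np.linalg.norm(c - c0)
        if len(mon):
            g = min(g, np.min(np.linalg.norm(mon - c, axis=1)) - exclusion)
        return g

    if np.linalg.norm(p - c0) > R:
        raise ValueError("probe lies outside Omega")
    g_p = gap(p)
    if g_p <= 0.0:
        return 0.0
    if len(mon) == 0:
        return R

    # variables x = (cx, cy, cz, r); maximize r subject to
    #   |c - m_i| - exclusion - r >= 0   (void of monomer hard cores)
    #   R - r - |c - c0| >= 0            (sphere inside Omega)
    #   r - |c - p| >= 0                 (sphere covers the probe)
    eps = 1e-12

    def mono_fun(x):
        return np.linalg.norm(mon - x[:3], axis=1) - exclusion - x[3]

    def mono_jac(x):
        d = x[:3] - mon
        n = np.maximum(np.linalg.norm(d, axis=1, keepdims=True), eps)
        return np.hstack([d / n, -np.ones((len(mon), 1))])

    def omega_fun(x):
        return np.array([R - x[3] - np.linalg.norm(x[:3] - c0)])

    def omega_jac(x):
        d = x[:3] - c0
        n = max(np.linalg.norm(d), eps)
        return np.concatenate([-d / n, [-1.0]])[None, :]

    def cover_fun(x):
        return np.array([x[3] - np.linalg.norm(x[:3] - p)])

    def cover_jac(x):
        d = x[:3] - p
        n = max(np.linalg.norm(d), eps)
        return np.concatenate([-d / n, [1.0]])[None, :]

    cons = [
        {"type": "ineq", "fun": mono_fun, "jac": mono_jac},
        {"type": "ineq", "fun": omega_fun, "jac": omega_jac},
        {"type": "ineq", "fun": cover_fun, "jac": cover_jac},
    ]
    best = g_p
    starts = [p, p + (c0 - p) * 0.3]
    for s0 in starts:
        x0 = np.concatenate([s0, [max(gap(s0), 1e-4)]])
        res = minimize(
            lambda x: -x[3],
            x0,
            jac=lambda x: np.array([0.0, 0.0, 0.0, -1.0]),
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 120, "ftol": 1e-10},
        )
        if res.x[3] > best:
            c, r = res.x[:3], res.x[3]
            # accept only genuinely feasible solutions
            if np.linalg.norm(c - p) <= r + 1e-7 and gap(c) >= r - 1e-7:
                best = r
    return float(best)


def pore_size_distribution(
    monomers: np.ndarray,
    region_radius: float,
    n_probes: int = 1000,
    rng: np.random.Generator | int = 0,
    center: np.ndarray = None,
    exclusion: float = 0.5,
) -> PoreSizeDistribution:
    """Sample the pore-size function at uniform probe points inside Omega.

    ``monomers`` are unwrapped coordinates relative to the same origin as
    ``center`` (default the origin).  Probes falling inside a monomer hard
    core contribute pore size 0.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c0 = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    # uniform in the ball
    u = rng.normal(size=(n_probes, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    probes = c0 + u * (region_radius * rng.random(n_probes) ** (1.0 / 3.0))[:, None]
    radii = np.array(
        [pore_size_at(p, monomers, region_radius, center=c0, exclusion=exclusion) for p in probes]
    )
    return PoreSizeDistribution(radii=radii)


def pore_size_grid_oracle(
    probe: np.ndarray,
    monomers: np.ndarray,
    region_radius: float,
    center: np.ndarray = None,
    exclusion: float = 0.5,
    grid_step: float = 0.05,
) -> float:
    """Exhaustive lattice search over sphere centers (reference implementation)."""
    p = np.asarray(probe, dtype=float)
    mon = np.asarray(monomers, dtype=float).reshape(-1, 3)
    c0 = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    R = float(region_radius)
    ax = np.arange(-R, R + grid_step, grid_step)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + c0
    g = R - np.linalg.norm(centers - c0, axis=1)
    for m in mon:
        g = np.minimum(g, np.linalg.norm(centers - m, axis=1) - exclusion)
    ok = g >= np.linalg.norm(centers - p, axis=1)
    return float(np.max(g[ok])) if np.any(ok) else 0.0


# --------------------------------------------------------------- scaling fits


@dataclass
class ScalingFit:
    """Parameters of y = k * x^(-e) + c (decay) or y = k * x^(+e) + c (growth)."""

    amplitude: float
    exponent: float
    offset: float
    stderr: tuple[float, float, float]
    form: str
    exponent_identifiable: bool = True
    x_range: tuple[float, float] = (np.nan, np.nan)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        s = -1.0 if self.form == "decay" else 1.0
        return self.amplitude * x ** (s * self.exponent) + self.offset


def fit_power_law_offset(x, y, form: str = "decay", sigma=None) -> ScalingFit:
    """Nonlinear least squares for a power law with an additive asymptote.

    Standard errors come from the Jacobian-based covariance.  A flat y is
    flagged (exponent unidentifiable) with offset = mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if form not in ("decay", "growth"):
        raise ValueError("form must be 'decay' or 'growth'")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct x values")
    s = -1.0 if form == "decay" else 1.0

    if np.ptp(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        return ScalingFit(0.0, 0.0, float(np.mean(y)), (np.nan, np.nan, np.nan),
                          form, exponent_identifiable=False, x_range=(x.min(), x.max()))

    def model(x, k, e, c):
        return k * x ** (s * e) + c

    # initial guess: offset from the asymptotic side, exponent from log-log slope
    order = np.argsort(x)
    xo, yo = x[order], y[order]
    c0 = yo[-1] if form == "decay" else yo[0]
    resid = np.abs(yo - c0) + 1e-12
    slope, icept = np.polyfit(np.log(xo), np.log(resid), 1)
    e0 = abs(slope)
    k0 = np.exp(icept) * np.sign(yo[0] - c0 if form == "decay" else yo[-1] - c0)
    try:
        popt, pcov = curve_fit(
            model, x, y, p0=[k0 if k0 != 0 else 1.0, max(e0, 0.1), c0],
            sigma=sigma, maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"power-law fit did not converge: {exc}") from exc
    err = np.sqrt(np.diag(pcov))
    return ScalingFit(
        amplitude=float(popt[0]),
        exponent=float(popt[1]),
        offset=float(popt[2]),
        stderr=(float(err[0]), float(err[1]), float(err[2])),
        form=form,
        x_range=(float(x.min()), float(x.max())),
    )
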