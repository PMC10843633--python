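"""Kinetic observables from single-particle trajectories.

Residence times and penetration lengths of molecules visiting the PSD,
binding times at attractive sites, local density around sites, escape
times from the domain center, the radially-conditioned mean square
displacement and the anomalous-exponent spectrum alpha(r).

Boundary crossings are detected at frame resolution: a crossing is dated
at the first frame on the new side of the boundary (no sub-frame
interpolation), so every duration is a multiple of the frame interval
with an O(frame interval) bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


# ------------------------------------------------------ residence episodes


@dataclass
class Episode:
    """One visit of a molecule inside Omega."""

    entry_time: float
    exit_time: float
    max_depth: float
    censored: bool = False

    @property
    def duration(self) -> float:
        return self.exit_time - self.entry_time


@dataclass
class EpisodeSet:
    """All visits of one molecule; censored episodes are excluded from means."""

    episodes: list

    def completed(self) -> list:
        return [e for e in self.episodes if not e.censored]

    def mean_residence(self) -> float:
        eps = self.completed()
        return float(np.mean([e.duration for e in eps])) if eps else np.nan

    def mean_penetration(self) -> float:
        eps = self.completed()
        return float(np.mean([e.max_depth for e in eps])) if eps else np.nan


def residence_and_penetration(
    radii: np.ndarray, times: np.ndarray, region_radius: float
) -> EpisodeSet:
    """Detect visits of one molecule from its radial track |x(t) - r_CM(t)|.

    Entry is the first frame with r < R after a frame outside, exit the
    first frame back outside.  A visit already in progress at the first
    frame or still in progress at the last frame is flagged censored.
    Penetration depth is max(R - r) over the visit.
    """
    r = np.asarray(radii, dtype=float)
    t = np.asarray(times, dtype=float)
    if r.shape != t.shape or r.ndim != 1:
        raise ValueError("radii and times must be matching 1-D arrays")
    inside = r < region_radius
    episodes: list[Episode] = []
    k = 0
    n = len(r)
    while k < n:
        if not inside[k]:
            k += 1
            continue
        start = k
        while k < n and inside[k]:
            k += 1
        depth = float(np.max(region_radius - r[start:k]))
        left_censored = start == 0
        right_censored = k == n
        exit_time = t[k] if k < n else t[-1]
        episodes.append(
            Episode(
                entry_time=float(t[start]),
                exit_time=float(exit_time),
                max_depth=depth,
                censored=left_censored or right_censored,
            )
        )
    return EpisodeSet(episodes=episodes)


def pooled_residence_stats(episode_sets: list) -> dict:
    """Episode-averaged <tau_in>, <L_in> with standard errors over all molecules."""
    durs = [e.duration for s in episode_sets for e in s.completed()]
    deps = [e.max_depth for s in episode_sets for e in s.completed()]
    out = {"n_episodes": len(durs)}
    for key, vals in (("tau_in", durs), ("L_in", deps)):
        if vals:
            out[key] = float(np.mean(vals))
            out[key + "_se"] = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        else:
            out[key] = np.nan
            out[key + "_se"] = np.nan
    return out


# ------------------------------------------------------------ binding times


@dataclass
class BindingIntervals:
    """Contiguous bound intervals (in time units); censored ones touch a run end."""

    durations: np.ndarray
    censored: np.ndarray

    def completed(self) -> np.ndarray:
        return self.durations[~self.censored]

    def mean(self) -> float:
        c = self.completed()
        return float(np.mean(c)) if len(c) else np.nan

    def stderr(self) -> float:
        c = self.completed()
        return float(np.std(c, ddof=1) / np.sqrt(len(c))) if len(c) > 1 else np.nan


def binding_times(registry: np.ndarray, times: np.ndarray) -> BindingIntervals:
    """Contiguous bound intervals per molecule from the per-frame bond registry.

    ``registry`` is (n_frames, n_mol) with the bound site index or -1.  An
    interval of k consecutive bound frames counts k frame intervals; an
    interval touching the start or end of the run is censored.
    """
    reg = np.asarray(registry)
    t = np.asarray(times, dtype=float)
    if reg.ndim != 2 or len(t) != len(reg):
        raise ValueError("registry must be (n_frames, n_mol) matching times")
    if len(t) > 1:
        frame_dt = float(np.mean(np.diff(t)))
    else:
        frame_dt = 1.0
    durations, censored = [], []
    for m in range(reg.shape[1]):
        bound = reg[:, m] >= 0
        k = 0
        n = len(bound)
        while k < n:
            if not bound[k]:
                k += 1
                continue
            start = k
            while k < n and bound[k]:
                k += 1
            durations.append((k - start) * frame_dt)
            censored.append(start == 0 or k == n)
    return BindingIntervals(
        durations=np.array(durations, dtype=float),
        censored=np.array(censored, dtype=bool),
    )


# -------------------------------------------------- local density near sites


def local_density_at_sites(
    molecule_frames: np.ndarray,
    site_frames: np.ndarray,
    box: float,
    probe_radius: float,
) -> float:
    """Ratio rho_b / rho of molecule density near binding sites to the bulk.

    ``molecule_frames`` is (F, n_mol, 3) and ``site_frames`` (F, n_sites, 3)
    in the same coordinates; counting uses the minimum image.  Returns the
    frame- and site-averaged count per probe-sphere volume divided by the
    global molecule density N_mol / V.
    """
    mols = np.asarray(molecule_frames, dtype=float)
    sites = np.asarray(site_frames, dtype=float)
    if mols.ndim == 2:
        mols = mols[None]
    if sites.ndim == 2:
        sites = sites[None]
    d = mols[:, None, :, :] - sites[:, :, None, :]
    d -= box * np.round(d / box)
    within = np.sum(np.sum(d**2, axis=-1) < probe_radius**2, axis=2)  # (F, n_sites)
    v_probe = 4.0 / 3.0 * np.pi * probe_radius**3
    rho_local = within.mean() / v_probe
    rho_global = mols.shape[1] / box**3
    return float(rho_local / rho_global)


# --------------------------------------------------------------- escape times


@dataclass
class EscapeTimes:
    """First-passage times out of Omega; censored runs never escaped."""

    times: np.ndarray
    censored: np.ndarray

    def mean(self) -> float:
        c = self.times[~self.censored]
        return float(np.mean(c)) if len(c) else np.nan

    def stderr(self) -> float:
        c = self.times[~self.censored]
        return float(np.std(c, ddof=1) / np.sqrt(len(c))) if len(c) > 1 else np.nan

    @property
    def all_censored(self) -> bool:
        return bool(np.all(self.censored))

    def lower_bound(self) -> float:
        """Mean over all runs, censored at run length (a lower bound on <tau_e>)."""
        return float(np.mean(self.times))


def escape_times(radii: np.ndarray, times: np.ndarray, region_radius: float) -> EscapeTimes:
    """First time each radial track exceeds R, relative to its start time.

    ``radii`` is (n_traj, n_frames) of distances to the domain center; each
    trajectory must start inside Omega (molecules are released at the CM).
    Trajectories that never leave are censored at the run length.
    """
    r = np.atleast_2d(np.asarray(radii, dtype=float))
    t = np.asarray(times, dtype=float)
    if r.shape[1] != len(t):
        raise ValueError("radii and times length mismatch")
    if np.any(r[:, 0] > region_radius):
        raise ValueError("a trajectory starts outside Omega; escape time undefined")
    out = np.empty(r.shape[0])
    cens = np.zeros(r.shape[0], dtype=bool)
    outside = r > region_radius
    for i in range(r.shape[0]):
        idx = np.argmax(outside[i])
        if outside[i, idx]:
            out[i] = t[idx] - t[0]
        else:
            out[i] = t[-1] - t[0]
            cens[i] = True
    return EscapeTimes(times=out, censored=cens)


# ------------------------------------------------------------ conditional MSD


@dataclass
class ConditionalMSD:
    """MSD(tau | r): lag-time curves stratified by the starting radius annulus."""

    annulus_edges: np.ndarray
    lags: np.ndarray
    msd: np.ndarray  # (n_annuli, n_lags), NaN where no samples
    counts: np.ndarray

    @property
    def annulus_centers(self) -> np.ndarray:
        return 0.5 * (self.annulus_edges[:-1] + self.annulus_edges[1:])


def conditional_msd(
    tracks: np.ndarray,
    times: np.ndarray,
    dr: float,
    lags: np.ndarray | None = None,
    r_max: float | None = None,
    box: float | None = None,
    radii: np.ndarray | None = None,
) -> ConditionalMSD:
    """Radially-conditioned MSD of an ensemble of tracks.

    ``tracks`` is (n_traj, n_frames, 3) in the frame whose origin defines
    the radial coordinate (for PSD analyses: relative to the chain CM).
    For each annulus A_r = (r, r + dr) and lag tau, averages
    |x(t+tau) - x(t)|^2 over every (trajectory, t) pair with x(t) in A_r.
    Empty annuli give NaN, not zero.  With ``box`` set, displacements are
    folded by minimum image (for tracks wrapped into a periodic box; the
    lag window must then be short enough that true displacements stay
    below box/2).  ``radii`` (n_traj, n_frames) overrides the conditioning
    radius — pass the folded distance to the domain center while keeping
    ``tracks`` unwrapped so long-lag displacements stay exact.
    """
    x = np.asarray(tracks, dtype=float)
    if x.ndim == 2:
        x = x[None]
    t = np.asarray(times, dtype=float)
    if dr <= 0:
        raise ValueError("dr must be positive")
    r0 = np.linalg.norm(x, axis=-1) if radii is None else np.asarray(radii, dtype=float)
    if r0.shape != x.shape[:2]:
        raise ValueError("radii must have shape (n_traj, n_frames)")
    if r_max is None:
        r_max = float(r0.max()) + dr
    edges = np.arange(0.0, r_max + dr, dr)
    n_ann = len(edges) - 1
    if lags is None:
        lags = np.arange(1, min(len(t), 51))
    lags = np.asarray(lags, dtype=int)
    msd = np.zeros((n_ann, len(lags)))
    counts = np.zeros((n_ann, len(lags)), dtype=np.int64)
    for li, lag in enumerate(lags):
        if lag >= x.shape[1]:
            continue
        d = x[:, lag:] - x[:, :-lag]
        if box is not None:
            d -= box * np.round(d / box)
        disp2 = np.sum(d**2, axis=-1)
        bins = np.minimum((r0[:, :-lag] / dr).astype(int), n_ann - 1)
        np.add.at(msd[:, li], bins.ravel(), disp2.ravel())
        np.add.at(counts[:, li], bins.ravel(), 1)
    with np.errstate(invalid="ignore"):
        msd = np.where(counts > 0, msd / np.maximum(counts, 1), np.nan)
    frame_dt = float(np.mean(np.diff(t))) if len(t) > 1 else 1.0
    return ConditionalMSD(
        annulus_edges=edges,
        lags=lags * frame_dt,
        msd=msd,
        counts=counts,
    )


# ------------------------------------------------------ anomalous exponents


@dataclass
class AlphaSpectrum:
    """Anomalous exponent alpha(r) and amplitude D_inf(r) from MSD ~ D_inf tau^alpha."""

    radii: np.ndarray
    alpha: np.ndarray
    d_inf: np.ndarray
    window: tuple[float, float]

    def mean_alpha_in(self, r_lo: float, r_hi: float) -> float:
        sel = (self.radii >= r_lo) & (self.radii < r_hi) & np.isfinite(self.alpha)
        if not np.any(sel):
            return np.nan
        return float(np.mean(self.alpha[sel]))


def anomalous_exponent(
    cmsd: ConditionalMSD, window: tuple[float, float], min_points: int = 4
) -> AlphaSpectrum:
    """Log-log slope of MSD(tau | r) over a lag window, per annulus.

    Annuli with fewer than ``min_points`` valid lags in the window give NaN.
    """
    lo, hi = window
    sel = (cmsd.lags >= lo) & (cmsd.lags <= hi)
    if sel.sum() < min_points:
        raise ValueError("fit window contains fewer lags than min_points")
    alphas = np.full(len(cmsd.annulus_centers), np.nan)
    dinfs = np.full(len(cmsd.annulus_centers), np.nan)
    for a in range(cmsd.msd.shape[0]):
        y = cmsd.msd[a, sel]
        tau = cmsd.lags[sel]
        ok = np.isfinite(y) & (y > 0) & (cmsd.counts[a, sel] > 0)
        if ok.sum() < min_points:
            continue
        slope, icept = np.polyfit(np.log(tau[ok]), np.log(y[ok]), 1)
        alphas[a] = slope
        dinfs[a] = np.exp(icept)
    return AlphaSpectrum(
        radii=cmsd.annulus_centers, alpha=alphas, d_inf=dinfs, window=(lo, hi)
    )
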