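"""Numba kernels: neighbor lists, forces, energies, and the Langevin loop.

Positions are stored unwrapped.  Non-bonded pair terms use the minimum-image
convention; intramolecular terms (FENE, bending, cross-link springs) act on
direct unwrapped differences, so the chain stays a contiguous object.

Status codes returned by the kernels:
0 ok, 1 FENE bond overstretched (r >= R0), 2 non-finite coordinate,
3 neighbor-list overflow.
"""

from __future__ import annotations

import numba as nb
import numpy as np

STATUS_OK = 0
STATUS_OVERSTRETCH = 1
STATUS_NONFINITE = 2
STATUS_OVERFLOW = 3


@nb.njit(cache=True, inline="always")
def _min_image(d, L):
    return d - L * np.round(d / L)


@nb.njit(cache=True, fastmath=True)
def build_pair_list(pos, L, rlist, pairs):
    """Fill ``pairs`` with all i<j within ``rlist`` (minimum image).

    Cell-linked list when the box holds >= 3 cells per side, otherwise an
    exact O(N^2) sweep.  Returns the pair count, or -1 on overflow.
    """
    N = pos.shape[0]
    r2max = rlist * rlist
    maxp = pairs.shape[0]
    count = 0
    ncell = int(L / rlist)
    if ncell < 3:
        for i in range(N - 1):
            for j in range(i + 1, N):
                dx = _min_image(pos[i, 0] - pos[j, 0], L)
                dy = _min_image(pos[i, 1] - pos[j, 1], L)
                dz = _min_image(pos[i, 2] - pos[j, 2], L)
                if dx * dx + dy * dy + dz * dz < r2max:
                    if count >= maxp:
                        return -1
                    pairs[count, 0] = i
                    pairs[count, 1] = j
                    count += 1
        return count

    inv = ncell / L
    head = np.full(ncell * ncell * ncell, -1, np.int32)
    nxt = np.empty(N, np.int32)
    cx = np.empty(N, np.int32)
    cy = np.empty(N, np.int32)
    cz = np.empty(N, np.int32)
    for i in range(N):
        ix = int((pos[i, 0] - L * np.floor(pos[i, 0] / L)) * inv) % ncell
        iy = int((pos[i, 1] - L * np.floor(pos[i, 1] / L)) * inv) % ncell
        iz = int((pos[i, 2] - L * np.floor(pos[i, 2] / L)) * inv) % ncell
        cx[i] = ix
        cy[i] = iy
        cz[i] = iz
        c = (ix * ncell + iy) * ncell + iz
        nxt[i] = head[c]
        head[c] = i

    # half-shell of neighbor-cell offsets (13) + the cell itself
    offs = np.array(
        [
            (0, 0, 0),
            (1, 0, 0),
            (1, 1, 0),
            (0, 1, 0),
            (-1, 1, 0),
            (1, 0, 1),
            (1, 1, 1),
            (0, 1, 1),
            (-1, 1, 1),
            (-1, 0, 1),
            (-1, -1, 1),
            (0, -1, 1),
            (1, -1, 1),
            (0, 0, 1),
        ],
        dtype=np.int64,
    )
    for ix in range(ncell):
        for iy in range(ncell):
            for iz in range(ncell):
                c1 = (ix * ncell + iy) * ncell + iz
                for k in range(offs.shape[0]):
                    jx = (ix + offs[k, 0]) % ncell
                    jy = (iy + offs[k, 1]) % ncell
                    jz = (iz + offs[k, 2]) % ncell
                    c2 = (jx * ncell + jy) * ncell + jz
                    i = head[c1]
                    while i >= 0:
                        if k == 0:
                            j = nxt[i]
                        else:
                            j = head[c2]
                        while j >= 0:
                            dx = _min_image(pos[i, 0] - pos[j, 0], L)
                            dy = _min_image(pos[i, 1] - pos[j, 1], L)
                            dz = _min_image(pos[i, 2] - pos[j, 2], L)
                            if dx * dx + dy * dy + dz * dz < r2max:
                                if count >= maxp:
                                    return -1
                                if i < j:
                                    pairs[count, 0] = i
                                    pairs[count, 1] = j
                                else:
                                    pairs[count, 0] = j
                                    pairs[count, 1] = i
                                count += 1
                            j = nxt[j]
                        i = nxt[i]
    return count


@nb.njit(cache=True, fastmath=True)
def compute_forces(
    pos,
    frc,
    n_mon,
    pairs,
    n_pairs,
    cross_links,
    bound_site,
    L,
    sigma,
    eps,
    R0,
    kfene,
    ktheta,
    krc,
    epsb,
    bindcut,
):
    """Analytic forces for the full Hamiltonian; returns a status code."""
    N = pos.shape[0]
    for i in range(N):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0
    s2 = sigma * sigma
    rc2 = 2.0 ** (1.0 / 3.0) * s2  # WCA cutoff squared

    # WCA repulsion over all pairs within cutoff (bonded pairs included),
    # except a molecule and the binding site it is currently attached to.
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if j >= n_mon and i < n_mon and bound_site[j - n_mon] == i:
            continue
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2 and r2 > 0.0:
            sr6 = (s2 / r2) ** 3
            fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
            frc[i, 0] += fmag * dx
            frc[i, 1] += fmag * dy
            frc[i, 2] += fmag * dz
            frc[j, 0] -= fmag * dx
            frc[j, 1] -= fmag * dy
            frc[j, 2] -= fmag * dz

    # FENE backbone
    R02 = R0 * R0
    for b in range(n_mon - 1):
        i = b
        j = b + 1
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= R02:
            return STATUS_OVERSTRETCH
        fmag = -kfene / (1.0 - r2 / R02)
        frc[i, 0] += fmag * dx
        frc[i, 1] += fmag * dy
        frc[i, 2] += fmag * dz
        frc[j, 0] -= fmag * dx
        frc[j, 1] -= fmag * dy
        frc[j, 2] -= fmag * dz

    # bending on interior monomers
    for m in range(1, n_mon - 1):
        b1x = pos[m, 0] - pos[m - 1, 0]
        b1y = pos[m, 1] - pos[m - 1, 1]
        b1z = pos[m, 2] - pos[m - 1, 2]
        b2x = pos[m + 1, 0] - pos[m, 0]
        b2y = pos[m + 1, 1] - pos[m, 1]
        b2z = pos[m + 1, 2] - pos[m, 2]
        n1s = b1x * b1x + b1y * b1y + b1z * b1z
        n2s = b2x * b2x + b2y * b2y + b2z * b2z
        if n1s == 0.0 or n2s == 0.0:
            continue
        n1 = np.sqrt(n1s)
        n2 = np.sqrt(n2s)
        dot = b1x * b2x + b1y * b2y + b1z * b2z
        c = dot / (n1 * n2)
        # dU/db1 = -ktheta * (b2/(n1 n2) - c b1 / n1^2), etc.
        g1x = -ktheta * (b2x / (n1 * n2) - c * b1x / n1s)
        g1y = -ktheta * (b2y / (n1 * n2) - c * b1y / n1s)
        g1z = -ktheta * (b2z / (n1 * n2) - c * b1z / n1s)
        g2x = -ktheta * (b1x / (n1 * n2) - c * b2x / n2s)
        g2y = -ktheta * (b1y / (n1 * n2) - c * b2y / n2s)
        g2z = -ktheta * (b1z / (n1 * n2) - c * b2z / n2s)
        # F_{m-1} = +dU/db1, F_{m+1} = -dU/db2, F_m balances
        frc[m - 1, 0] += g1x
        frc[m - 1, 1] += g1y
        frc[m - 1, 2] += g1z
        frc[m + 1, 0] -= g2x
        frc[m + 1, 1] -= g2y
        frc[m + 1, 2] -= g2z
        frc[m, 0] += g2x - g1x
        frc[m, 1] += g2y - g1y
        frc[m, 2] += g2z - g1z

    # harmonic cross-link springs
    for k in range(cross_links.shape[0]):
        i = cross_links[k, 0]
        j = cross_links[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        frc[i, 0] -= krc * dx
        frc[i, 1] -= krc * dy
        frc[i, 2] -= krc * dz
        frc[j, 0] += krc * dx
        frc[j, 1] += krc * dy
        frc[j, 2] += krc * dz

    # attractive full LJ between each bound molecule and its site
    bc2 = bindcut * bindcut
    n_mol = N - n_mon
    for m in range(n_mol):
        s = bound_site[m]
        if s < 0:
            continue
        i = n_mon + m
        dx = _min_image(pos[i, 0] - pos[s, 0], L)
        dy = _min_image(pos[i, 1] - pos[s, 1], L)
        dz = _min_image(pos[i, 2] - pos[s, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < bc2 and r2 > 0.0:
            sr6 = (s2 / r2) ** 3
            fmag = 24.0 * epsb * (2.0 * sr6 * sr6 - sr6) / r2
            frc[i, 0] += fmag * dx
            frc[i, 1] += fmag * dy
            frc[i, 2] += fmag * dz
            frc[s, 0] -= fmag * dx
            frc[s, 1] -= fmag * dy
            frc[s, 2] -= fmag * dz
    return STATUS_OK


@nb.njit(cache=True)
def compute_energy(
    pos,
    n_mon,
    pairs,
    n_pairs,
    cross_links,
    bound_site,
    L,
    sigma,
    eps,
    R0,
    kfene,
    ktheta,
    krc,
    epsb,
    bindcut,
):
    """Total potential energy; returns (energy, status)."""
    N = pos.shape[0]
    s2 = sigma * sigma
    rc2 = 2.0 ** (1.0 / 3.0) * s2
    e = 0.0
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if j >= n_mon and i < n_mon and bound_site[j - n_mon] == i:
            continue
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2 and r2 > 0.0:
            sr6 = (s2 / r2) ** 3
            e += 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
    R02 = R0 * R0
    for b in range(n_mon - 1):
        dx = pos[b, 0] - pos[b + 1, 0]
        dy = pos[b, 1] - pos[b + 1, 1]
        dz = pos[b, 2] - pos[b + 1, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= R02:
            return np.inf, STATUS_OVERSTRETCH
        e += -0.5 * kfene * R02 * np.log(1.0 - r2 / R02)
    for m in range(1, n_mon - 1):
        b1x = pos[m, 0] - pos[m - 1, 0]
        b1y = pos[m, 1] - pos[m - 1, 1]
        b1z = pos[m, 2] - pos[m - 1, 2]
        b2x = pos[m + 1, 0] - pos[m, 0]
        b2y = pos[m + 1, 1] - pos[m, 1]
        b2z = pos[m + 1, 2] - pos[m, 2]
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 == 0.0 or n2 == 0.0:
            continue
        c = (b1x * b2x + b1y * b2y + b1z * b2z) / (n1 * n2)
        e += ktheta * (1.0 - c)
    for k in range(cross_links.shape[0]):
        i = cross_links[k, 0]
        j = cross_links[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        e += 0.5 * krc * (dx * dx + dy * dy + dz * dz)
    bc2 = bindcut * bindcut
    src6 = (s2 / bc2) ** 3
    shift = 4.0 * epsb * (src6 * src6 - src6)
    for m in range(N - n_mon):
        s = bound_site[m]
        if s < 0:
            continue
        i = n_mon + m
        dx = _min_image(pos[i, 0] - pos[s, 0], L)
        dy = _min_image(pos[i, 1] - pos[s, 1], L)
        dz = _min_image(pos[i, 2] - pos[s, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < bc2 and r2 > 0.0:
            sr6 = (s2 / r2) ** 3
            e += 4.0 * epsb * (sr6 * sr6 - sr6) - shift
    return e, STATUS_OK


@nb.njit(cache=True)
def update_bindings_kernel(pos, n_mon, sites, bound_site, L, dcap):
    """Release beyond d_capture, then attach free molecules to nearest site.

    Ties at equal distance resolve to the lowest site index (sites are
    scanned in ascending order with a strict inequality).
    """
    n_mol = pos.shape[0] - n_mon
    for m in range(n_mol):
        i = n_mon + m
        s = bound_site[m]
        if s >= 0:
            dx = _min_image(pos[i, 0] - pos[s, 0], L)
            dy = _min_image(pos[i, 1] - pos[s, 1], L)
            dz = _min_image(pos[i, 2] - pos[s, 2], L)
            if np.sqrt(dx * dx + dy * dy + dz * dz) > dcap:
                bound_site[m] = -1
        if bound_site[m] < 0:
            best = -1
            bestd = dcap
            for k in range(sites.shape[0]):
                s = sites[k]
                dx = _min_image(pos[i, 0] - pos[s, 0], L)
                dy = _min_image(pos[i, 1] - pos[s, 1], L)
                dz = _min_image(pos[i, 2] - pos[s, 2], L)
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if d < bestd:
                    bestd = d
                    best = s
            bound_site[m] = best


@nb.njit(cache=True, fastmath=True)
def run_chunk(
    pos,
    vel,
    n_mon,
    cross_links,
    sites,
    bound_site,
    L,
    sigma,
    eps,
    mass,
    R0,
    kfene,
    ktheta,
    krc,
    epsb,
    bindcut,
    gamma,
    dt,
    dcap,
    noise,
    step0,
    frame_interval,
    frames,
    times,
    registry,
    t0,
):
    """Integrate len(noise) GJF Langevin velocity-Verlet steps.

    ``noise`` holds the pre-scaled thermal kicks beta ~ N(0, 2 gamma m kT dt)
    for each step (all zeros for the NVE limit).  ``step0`` is the global
    step index of the first step in this chunk; frames are recorded whenever
    (global step + 1) is a multiple of ``frame_interval``.  ``frames`` may be
    zero-length (equilibration).  The Gronbech-Jensen/Farago discretization
    samples the configurational Boltzmann distribution correctly at finite
    dt and reduces to plain velocity Verlet when gamma = 0.
    """
    N = pos.shape[0]
    n_steps = noise.shape[0]
    skin = 0.4 * sigma
    rc_nb = 2.0 ** (1.0 / 6.0) * sigma
    rlist = rc_nb + skin
    half_skin2 = (0.5 * skin) ** 2
    maxpairs = 60 * N + 1024
    pairs = np.empty((maxpairs, 2), np.int32)
    ref = pos.copy()
    frc = np.empty((N, 3))
    frc_new = np.empty((N, 3))

    n_pairs = build_pair_list(pos, L, rlist, pairs)
    if n_pairs < 0:
        return STATUS_OVERFLOW
    st = compute_forces(
        pos, frc, n_mon, pairs, n_pairs, cross_links, bound_site, L,
        sigma, eps, R0, kfene, ktheta, krc, epsb, bindcut,
    )
    if st != STATUS_OK:
        return st

    bcoef = 1.0 / (1.0 + 0.5 * gamma * dt)
    acoef = (1.0 - 0.5 * gamma * dt) * bcoef
    c_pos_v = bcoef * dt
    c_pos_f = bcoef * dt * dt / (2.0 * mass)
    c_pos_b = bcoef * dt / (2.0 * mass)
    c_vel_f = dt / (2.0 * mass)
    c_vel_b = bcoef / mass
    has_sites = sites.shape[0] > 0

    for step in range(n_steps):
        maxd2 = 0.0
        for i in range(N):
            for d in range(3):
                pos[i, d] += c_pos_v * vel[i, d] + c_pos_f * frc[i, d] + c_pos_b * noise[step, i, d]
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        # refresh the Verlet list once something moved more than half the skin
        if maxd2 > half_skin2:
            if not np.isfinite(pos).all():
                return STATUS_NONFINITE
            n_pairs = build_pair_list(pos, L, rlist, pairs)
            if n_pairs < 0:
                return STATUS_OVERFLOW
            ref[:, :] = pos
        st = compute_forces(
            pos, frc_new, n_mon, pairs, n_pairs, cross_links, bound_site, L,
            sigma, eps, R0, kfene, ktheta, krc, epsb, bindcut,
        )
        if st != STATUS_OK:
            return st
        for i in range(N):
            for d in range(3):
                vel[i, d] = (
                    acoef * vel[i, d]
                    + c_vel_f * (acoef * frc[i, d] + frc_new[i, d])
                    + c_vel_b * noise[step, i, d]
                )
                frc[i, d] = frc_new[i, d]
        if has_sites:
            update_bindings_kernel(pos, n_mon, sites, bound_site, L, dcap)
        gstep = step0 + step + 1
        if frames.shape[0] > 0 and gstep % frame_interval == 0:
            k = gstep // frame_interval - 1
            frames[k, :, :] = pos
            times[k] = t0 + gstep * dt
            if registry.shape[0] > 0:
                registry[k, :] = bound_site
    return STATUS_OK
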