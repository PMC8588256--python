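"""Numba kernels for the Langevin dynamics hot loop.

One fused routine advances the chain by a block of BAOAB steps: harmonic
bonds, harmonic angles, chain-chain WCA (bonded pairs excluded), chain-wall
WCA against a static cell list of wall beads, an optional implicit
cylindrical wall (used while shrink-confining chains), the per-bead
external pull along z, and the tethered-bead freeze.  The Python layer in
:mod:`helknot.dynamics` orchestrates sampling, topology checks and flips
between blocks.

The kernel RNG is numba's internal nopython-mode state: it is seeded once
per trajectory via :func:`seed_rng` and the stream then continues across
blocks, so trajectories are reproducible given (seed, block schedule).
``noise_reflect`` multiplies the Gaussian kicks componentwise; the default
(1, 1, 1) is the physical case, while (1, -1, 1) realizes the mirrored
noise stream used by the reflection-equivariance tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _wca_scalar_force(r, eps, sig):
    """-dU/dr of the WCA potential (0 beyond cutoff)."""
    if r >= WCA_CUTOFF * sig:
        return 0.0
    sr2 = (sig / r) ** 2
    sr6 = sr2 * sr2 * sr2
    return 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r


@njit(cache=True)
def compute_forces(pos, f, circular,
                   k_s, r0, k_theta, eps, sig,
                   fext, fsign, f_end,
                   wall, cell_start, cell_count, cell_items,
                   grid_origin, grid_ncell, grid_csize,
                   periodic_z, period_len,
                   cyl_radius, k_anchor, anchor0, anchor1):
    n = pos.shape[0]
    cutoff = WCA_CUTOFF * sig
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = fext * fsign
    if f_end != 0.0 and not circular:
        f[0, 2] -= f_end
        f[n - 1, 2] += f_end
    if k_anchor > 0.0 and not circular:
        for d in range(3):
            f[0, d] -= k_anchor * (pos[0, d] - anchor0[d])
            f[n - 1, d] -= k_anchor * (pos[n - 1, d] - anchor1[d])
    # bonds
    nb = n if circular else n - 1
    for i in range(nb):
        j = (i + 1) % n
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            return -1 - i  # coincident bonded beads
        fr = -2.0 * k_s * (r - r0) / r
        f[j, 0] += fr * dx
        f[j, 1] += fr * dy
        f[j, 2] += fr * dz
        f[i, 0] -= fr * dx
        f[i, 1] -= fr * dy
        f[i, 2] -= fr * dz
    # angles
    a_lo = 0 if circular else 1
    a_hi = n if circular else n - 1
    for b in range(a_lo, a_hi):
        ia = (b - 1) % n
        ic = (b + 1) % n
        ux = pos[ia, 0] - pos[b, 0]
        uy = pos[ia, 1] - pos[b, 1]
        uz = pos[ia, 2] - pos[b, 2]
        vx = pos[ic, 0] - pos[b, 0]
        vy = pos[ic, 1] - pos[b, 1]
        vz = pos[ic, 2] - pos[b, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-12 or nv < 1e-12:
            return -1 - b
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        st = np.sqrt(max(1.0 - ct * ct, 1e-14))
        coef = -k_theta * (theta - np.pi) / st  # (-dU/dtheta)/sin
        # dcos/da and dcos/dc
        dax = vx / (nu * nv) - ct * ux / (nu * nu)
        day = vy / (nu * nv) - ct * uy / (nu * nu)
        daz = vz / (nu * nv) - ct * uz / (nu * nu)
        dcx = ux / (nu * nv) - ct * vx / (nv * nv)
        dcy = uy / (nu * nv) - ct * vy / (nv * nv)
        dcz = uz / (nu * nv) - ct * vz / (nv * nv)
        fax = -coef * dax
        fay = -coef * day
        faz = -coef * daz
        fcx = -coef * dcx
        fcy = -coef * dcy
        fcz = -coef * dcz
        f[ia, 0] += fax
        f[ia, 1] += fay
        f[ia, 2] += faz
        f[ic, 0] += fcx
        f[ic, 1] += fcy
        f[ic, 2] += fcz
        f[b, 0] -= fax + fcx
        f[b, 1] -= fay + fcy
        f[b, 2] -= faz + fcz
    # chain-chain WCA (exclude bonded pairs)
    cut2 = cutoff * cutoff
    for i in range(n):
        for j in range(i + 2, n):
            if circular and i == 0 and j == n - 1:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cut2:
                continue
            r = np.sqrt(r2)
            if r < 1e-12:
                return -1000000 - i
            fr = _wca_scalar_force(r, eps, sig) / r
            f[j, 0] += fr * dx
            f[j, 1] += fr * dy
            f[j, 2] += fr * dz
            f[i, 0] -= fr * dx
            f[i, 1] -= fr * dy
            f[i, 2] -= fr * dz
    # chain-wall WCA via static cell list
    if wall.shape[0] > 0:
        nx = grid_ncell[0]
        ny = grid_ncell[1]
        nz = grid_ncell[2]
        for i in range(n):
            px = pos[i, 0]
            py = pos[i, 1]
            pz = pos[i, 2]
            if periodic_z:
                pz = pz % period_len
            ix = int(np.floor((px - grid_origin[0]) / grid_csize[0]))
            iy = int(np.floor((py - grid_origin[1]) / grid_csize[1]))
            iz = int(np.floor((pz - grid_origin[2]) / grid_csize[2]))
            if ix < -1 or ix > nx or iy < -1 or iy > ny:
                continue
            if (not periodic_z) and (iz < -1 or iz > nz):
                continue
            for ddx in range(-1, 2):
                cx = ix + ddx
                if cx < 0 or cx >= nx:
                    continue
                for ddy in range(-1, 2):
                    cy = iy + ddy
                    if cy < 0 or cy >= ny:
                        continue
                    for ddz in range(-1, 2):
                        cz = iz + ddz
                        if periodic_z:
                            cz = cz % nz
                        elif cz < 0 or cz >= nz:
                            continue
                        cid = cx + nx * (cy + ny * cz)
                        start = cell_start[cid]
                        cnt = cell_count[cid]
                        for kk in range(start, start + cnt):
                            w = cell_items[kk]
                            dx = pos[i, 0] - wall[w, 0]
                            dy = pos[i, 1] - wall[w, 1]
                            dz = pz - wall[w, 2]
                            if periodic_z:
                                dz -= period_len * np.rint(dz / period_len)
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 >= cut2:
                                continue
                            r = np.sqrt(r2)
                            if r < 1e-12:
                                return -2000000 - i
                            fr = _wca_scalar_force(r, eps, sig) / r
                            f[i, 0] += fr * dx
                            f[i, 1] += fr * dy
                            f[i, 2] += fr * dz
    # implicit cylindrical wall about the z axis; beads caught outside a
    # freshly shrunk wall get a bounded harmonic push inward instead of the
    # (divergent) WCA force so the integration stays stable
    if cyl_radius > 0.0:
        for i in range(n):
            rho = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
            gap = cyl_radius - rho
            if gap < cutoff and rho > 1e-9:
                if gap < 0.8:
                    fr = _wca_scalar_force(0.8, eps, sig) \
                        + 20.0 * (0.8 - gap)
                else:
                    fr = _wca_scalar_force(gap, eps, sig)
                f[i, 0] -= fr * pos[i, 0] / rho
                f[i, 1] -= fr * pos[i, 1] / rho
    return 0


@njit(cache=True)
def run_baoab(pos, vel, n_steps, dt, gamma, kT, mass, tether, circular,
              k_s, r0, k_theta, eps, sig,
              fext, fsign, f_end,
              wall, cell_start, cell_count, cell_items,
              grid_origin, grid_ncell, grid_csize,
              periodic_z, period_len, cyl_radius,
              k_anchor, anchor0, anchor1,
              reflect):
    """Advance the chain by ``n_steps`` BAOAB Langevin steps in place.

    Returns 0 on success or a negative code from the force routine
    (coincident beads).  ``tether < 0`` means no tether.
    """
    n = pos.shape[0]
    f = np.empty((n, 3))
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1) / mass)
    status = compute_forces(pos, f, circular, k_s, r0, k_theta, eps, sig,
                            fext, fsign, f_end, wall, cell_start, cell_count,
                            cell_items, grid_origin, grid_ncell, grid_csize,
                            periodic_z, period_len, cyl_radius,
                            k_anchor, anchor0, anchor1)
    if status != 0:
        return status
    half = 0.5 * dt
    for _ in range(n_steps):
        for i in range(n):
            if i == tether:
                continue
            vel[i, 0] += half * f[i, 0] / mass
            vel[i, 1] += half * f[i, 1] / mass
            vel[i, 2] += half * f[i, 2] / mass
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        for i in range(n):
            if i == tether:
                continue
            vel[i, 0] = c1 * vel[i, 0] + c2 * np.random.normal() * reflect[0]
            vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.normal() * reflect[1]
            vel[i, 2] = c1 * vel[i, 2] + c2 * np.random.normal() * reflect[2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        status = compute_forces(pos, f, circular, k_s, r0, k_theta, eps, sig,
                                fext, fsign, f_end, wall, cell_start,
                                cell_count, cell_items, grid_origin,
                                grid_ncell, grid_csize,
                                periodic_z, period_len, cyl_radius,
                                k_anchor, anchor0, anchor1)
        if status != 0:
            return status
        for i in range(n):
            if i == tether:
                continue
            vel[i, 0] += half * f[i, 0] / mass
            vel[i, 1] += half * f[i, 1] / mass
            vel[i, 2] += half * f[i, 2] / mass
    return 0


def build_wall_cells(wall: np.ndarray, periodic_z: bool, period_len: float,
                     cutoff: float = WCA_CUTOFF):
    """Static cell list over wall beads (CSR layout) for the kernel.

    Cells are cutoff-sized; for periodic channels the z cells tile the
    period exactly so neighbour lookups can wrap.
    """
    wall = np.ascontiguousarray(wall, dtype=float)
    if len(wall) == 0:
        return (wall, np.zeros(1, np.int64), np.zeros(1, np.int64),
                np.zeros(0, np.int64), np.zeros(3), np.ones(3, np.int64),
                np.ones(3))
    pad = 1e-6
    mins = wall.min(axis=0) - pad
    maxs = wall.max(axis=0) + pad
    origin = mins.copy()
    csize = np.empty(3)
    ncell = np.empty(3, np.int64)
    for d in (0, 1):
        span = maxs[d] - mins[d]
        ncell[d] = max(1, int(np.floor(span / cutoff)))
        csize[d] = span / ncell[d]
    if periodic_z:
        origin[2] = 0.0
        ncell[2] = max(1, int(np.floor(period_len / cutoff)))
        csize[2] = period_len / ncell[2]
        zw = wall[:, 2] % period_len
    else:
        span = maxs[2] - mins[2]
        ncell[2] = max(1, int(np.floor(span / cutoff)))
        csize[2] = span / ncell[2]
        zw = wall[:, 2]
    ix = np.floor((wall[:, 0] - origin[0]) / csize[0]).astype(np.int64)
    iy = np.floor((wall[:, 1] - origin[1]) / csize[1]).astype(np.int64)
    iz = np.floor((zw - origin[2]) / csize[2]).astype(np.int64)
    ix = np.clip(ix, 0, ncell[0] - 1)
    iy = np.clip(iy, 0, ncell[1] - 1)
    iz = np.clip(iz, 0, ncell[2] - 1)
    cid = ix + ncell[0] * (iy + ncell[1] * iz)
    order = np.argsort(cid, kind="stable")
    sorted_cid = cid[order]
    total = int(ncell[0] * ncell[1] * ncell[2])
    cell_start = np.zeros(total, np.int64)
    cell_count = np.zeros(total, np.int64)
    np.add.at(cell_count, sorted_cid, 1)
    cell_start[1:] = np.cumsum(cell_count)[:-1]
    return (wall, cell_start, cell_count, order.astype(np.int64),
            origin, ncell, csize)
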