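"""Numba kernels: Metropolis pixel-copy dynamics and the MMP PDE solver.

All kernels operate on flat primitive arrays so they can be jitted; the
object-level API lives in :mod:`invadopotts.cpm` and :mod:`invadopotts.mmp`.
Lattice arrays are indexed ``sigma[x, y]`` (C order) with cell ids
0 = fluid, -1 = fibre, >=1 = cell.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# 4-neighbourhood used for copy attempts, contact energies and perimeters
_DX = np.array([1, -1, 0, 0], dtype=np.int64)
_DY = np.array([0, 0, 1, -1], dtype=np.int64)


@njit(cache=True)
def _ptype(s: int) -> int:
    """Pixel type code from cell id: 0 fluid, 1 fibre, 2 cell."""
    if s > 0:
        return 2
    if s == 0:
        return 0
    return 1


@njit(cache=True, inline="always")
def attempt_delta_energy(
    sigma, x, y, nx, ny, J,
    areas, perim, polx, poly,
    lam_a, lam_p, a0, p0, mu0,
):
    """Local energy change for copying sigma[x, y] onto sigma[nx, ny].

    Returns (dE, dp_src, dp_tgt): the energy change and the perimeter-edge
    changes of the source and target cells, so an accepted move can update
    the cached perimeters without recounting.

    Only lattice-interior edges carry contact energy and perimeter; an edge
    is charged J[type1, type2] iff the two pixels belong to different
    domains (different sigma).  The motility bias is the self-propulsion
    work -mu0 * (polarity . copy_vector) for each affected cell, where the
    copy vector (target - source) has length one pixel (= L); polarity is
    held fixed during the MCS.
    """
    W, H = sigma.shape
    s_src = sigma[x, y]
    s_tgt = sigma[nx, ny]
    t_src = _ptype(s_src)
    t_tgt = _ptype(s_tgt)
    j_src = J[t_src]
    j_tgt = J[t_tgt]

    dE = 0.0
    n_src = 0
    n_tgt = 0
    deg = 0
    if 0 < nx < W - 1 and 0 < ny < H - 1:
        # interior fast path: all four neighbours of the target exist
        deg = 4
        for sn in (
            sigma[nx + 1, ny],
            sigma[nx - 1, ny],
            sigma[nx, ny + 1],
            sigma[nx, ny - 1],
        ):
            tn = _ptype(sn)
            if sn != s_tgt:
                dE -= j_tgt[tn]
                if sn == s_src:
                    n_src += 1
            else:
                n_tgt += 1
            if sn != s_src:
                dE += j_src[tn]
    else:
        for k in range(4):
            ux = nx + _DX[k]
            uy = ny + _DY[k]
            if ux < 0 or ux >= W or uy < 0 or uy >= H:
                continue
            deg += 1
            sn = sigma[ux, uy]
            tn = _ptype(sn)
            if sn != s_tgt:
                dE -= j_tgt[tn]
            if sn != s_src:
                dE += j_src[tn]
            if sn == s_src:
                n_src += 1
            if sn == s_tgt:
                n_tgt += 1

    dvx = float(nx - x)
    dvy = float(ny - y)
    dp_src = 0
    dp_tgt = 0
    if s_src > 0:
        a = areas[s_src]
        dE += lam_a * ((a + 1.0 - a0) ** 2 - (a - a0) ** 2)
        dp_src = deg - 2 * n_src
        p = perim[s_src]
        dE += lam_p * ((p + dp_src - p0) ** 2 - (p - p0) ** 2)
        dE -= mu0 * (polx[s_src] * dvx + poly[s_src] * dvy)
    if s_tgt > 0:
        a = areas[s_tgt]
        dE += lam_a * ((a - 1.0 - a0) ** 2 - (a - a0) ** 2)
        dp_tgt = 2 * n_tgt - deg
        p = perim[s_tgt]
        dE += lam_p * ((p + dp_tgt - p0) ** 2 - (p - p0) ** 2)
        dE -= mu0 * (polx[s_tgt] * dvx + poly[s_tgt] * dvy)
    return dE, dp_src, dp_tgt


@njit(cache=True)
def run_mcs_attempts(
    sigma, evolvable, J,
    areas, perim, sx, sy, polx, poly,
    lam_a, lam_p, a0, p0, t_m, mu0,
    pick, dirs, unif,
):
    """One Monte Carlo step: N copy attempts over the evolvable pixels.

    ``evolvable`` holds the flat indices of cell+fluid pixels at the start
    of the MCS (fibre pixels never evolve and are created/destroyed only at
    MCS boundaries, so the set is constant within the step).  A target that
    is a fibre pixel, off-lattice, or in the same domain as the source
    aborts the attempt; aborted attempts still count towards N.

    Randomness is supplied pre-drawn: ``pick`` (source index into
    evolvable), ``dirs`` (0..3 target direction) and ``unif`` (the
    Boltzmann uniform), one entry per attempt.

    Returns (n_attempts, n_accepted).
    """
    W, H = sigma.shape
    n = pick.shape[0]
    accepted = 0
    # dE above this is never accepted in double precision (exp underflows
    # against u >= 2^-53; u = 0 draws are astronomically rare and ignored),
    # so the Boltzmann test can be skipped entirely
    de_hopeless = 37.0 * t_m
    for a in range(n):
        idx = evolvable[pick[a]]
        x = idx // H
        y = idx % H
        k = dirs[a]
        if k == 0:
            nx = x + 1
            ny = y
        elif k == 1:
            nx = x - 1
            ny = y
        elif k == 2:
            nx = x
            ny = y + 1
        else:
            nx = x
            ny = y - 1
        if nx < 0 or nx >= W or ny < 0 or ny >= H:
            continue
        s_src = sigma[x, y]
        s_tgt = sigma[nx, ny]
        if s_tgt == -1 or s_src == s_tgt:
            continue
        dE, dp_src, dp_tgt = attempt_delta_energy(
            sigma, x, y, nx, ny, J, areas, perim, polx, poly,
            lam_a, lam_p, a0, p0, mu0,
        )
        if dE >= 0.0:
            if dE > de_hopeless:
                continue
            if unif[a] >= np.exp(-dE / t_m):
                continue
        # apply the copy
        sigma[nx, ny] = s_src
        if s_src > 0:
            areas[s_src] += 1.0
            sx[s_src] += nx
            sy[s_src] += ny
            perim[s_src] += dp_src
        if s_tgt > 0:
            areas[s_tgt] -= 1.0
            sx[s_tgt] -= nx
            sy[s_tgt] -= ny
            perim[s_tgt] += dp_tgt
        accepted += 1
    return n, accepted


@njit(cache=True, fastmath=True)
def mmp_substeps(
    field, contact_x, contact_y, lam_dt, r, decay_dt, n_substeps,
    x0, x1, y0, y1,
):
    """Run secretion + diffusion/decay forward-Euler substeps in place.

    Each 1-second substep first deposits ``lam_dt`` at every cell-contacted
    fibre pixel, then applies one explicit step of
    d[MMP]/dt = D lap[MMP] - delta [MMP] with a 5-point Laplacian and
    zero-flux boundaries (edge pixels exchange only with their in-lattice
    neighbours, which conserves mass exactly when decay is off).

    The update runs on the sub-box [x0, x1) x [y0, y1); callers guarantee
    the field is negligible outside it (pass the full extent for an exact
    whole-lattice update).

    Returns (substeps_run, max_value) for cadence/stability diagnostics.
    """
    cur = field
    buf = np.empty_like(field)
    keep = 1.0 - decay_dt - 4.0 * r
    for step in range(n_substeps):
        for c in range(contact_x.shape[0]):
            cur[contact_x[c], contact_y[c]] += lam_dt
        for i in range(x0, x1):
            im = i - 1 if i > x0 else i          # reflecting boundary:
            ip = i + 1 if i < x1 - 1 else i      # edge neighbour = centre
            row = cur[i]
            rowm = cur[im]
            rowp = cur[ip]
            out = buf[i]
            # branch-free interior sweep (edge columns handled after)
            for j in range(y0 + 1, y1 - 1):
                nv = keep * row[j] + r * (
                    rowm[j] + rowp[j] + row[j - 1] + row[j + 1]
                )
                out[j] = nv if nv > 0.0 else 0.0
            jl = y0
            jr = y1 - 1
            v = row[jl]
            right = row[jl + 1] if jr > jl else v
            nv = keep * v + r * (rowm[jl] + rowp[jl] + v + right)
            out[jl] = nv if nv > 0.0 else 0.0
            if jr > jl:
                v = row[jr]
                nv = keep * v + r * (rowm[jr] + rowp[jr] + row[jr - 1] + v)
                out[jr] = nv if nv > 0.0 else 0.0
        tmp = cur
        cur = buf
        buf = tmp
    vmax = 0.0
    for i in range(x0, x1):
        for j in range(y0, y1):
            if cur[i, j] > vmax:
                vmax = cur[i, j]
    if cur is not field:
        for i in range(x0, x1):
            for j in range(y0, y1):
                field[i, j] = cur[i, j]
    return n_substeps, vmax
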