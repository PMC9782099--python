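"""Numba-compiled inner loops (lattice MC, binary overlap, point-particle MC).

These kernels are performance plumbing only; all physical rules they
implement are defined (and independently validated) in the pure-Python
modules.  Coordinates passed to ``run_bead_jumps`` are unwrapped; the
occupancy grid operates on wrapped positions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "run_bead_jumps",
    "any_intermolecular_overlap",
    "run_pointlike_kernel",
    "grow_kernel",
]


@njit(cache=True, inline="always")
def _grid_update(grid, L, x, y, z, delta):
    for dx in range(-1, 2):
        gx = (x + dx) % L
        for dy in range(-1, 2):
            gy = (y + dy) % L
            for dz in range(-1, 2):
                grid[gx, gy, (z + dz) % L] += delta


@njit(cache=True)
def grow_kernel(
    grid,          # uint8[L,L,L] blocked counts; may already hold other molecules
    L,
    coords,        # int64[N,3] output buffer (unwrapped)
    segments,      # int64[n_seg,3] (parent, intermediate, child) in placement order
    dirs,          # int64[n_seg] +1/-1 preferred x direction per segment (rod bias)
    bonds,         # int64[108,3] allowed bond vectors
    ax, ay, az,    # anchor (first central)
    extent,        # slab span limit on y and z, or a huge value for none
    flip_prob,     # probability of flipping bx towards the subtree direction
    seg_attempts,
    max_restarts,
    budget_mult,   # backtracking budget = budget_mult * n_seg per restart
    anchor_jitter, # displace the anchor uniformly after a failed start
    seed,
):
    """Depth-first self-avoiding growth with backtracking and restarts.

    Places the two centrals (joined by a (3,0,0) bond) and then every
    segment as two identical randomly drawn bond vectors, rejecting
    placements that violate excluded volume (against the supplied grid,
    which may contain other molecules) or the slab window.  A jammed
    segment unwinds exponentially deeper on repeated failures; exhausted
    budgets trigger a whole-molecule restart with a jittered anchor.
    On success the molecule remains registered in ``grid``.

    Returns (ok, restarts_used, total_attempts).
    """
    np.random.seed(seed)
    n_seg = segments.shape[0]
    nb = bonds.shape[0]
    half = extent // 2
    total_attempts = 0

    for restart in range(max_restarts):
        sx, sy, sz = ax, ay, az
        if anchor_jitter > 0 and restart > 0:
            sx = ax + np.random.randint(-anchor_jitter, anchor_jitter + 1)
            sy = ay + np.random.randint(-anchor_jitter, anchor_jitter + 1)
            sz = az + np.random.randint(-anchor_jitter, anchor_jitter + 1)
        lo_y = sy - half
        lo_z = sz - half
        # centrals
        if grid[sx % L, sy % L, sz % L] != 0:
            total_attempts += 1
            continue
        if grid[(sx + 3) % L, sy % L, sz % L] != 0:
            total_attempts += 1
            continue
        coords[0, 0] = sx
        coords[0, 1] = sy
        coords[0, 2] = sz
        coords[1, 0] = sx + 3
        coords[1, 1] = sy
        coords[1, 2] = sz
        _grid_update(grid, L, sx, sy, sz, 1)
        _grid_update(grid, L, sx + 3, sy, sz, 1)

        idx = 0
        streak = 0
        budget = budget_mult * n_seg
        ok = True
        while idx < n_seg:
            parent = segments[idx, 0]
            inter = segments[idx, 1]
            child = segments[idx, 2]
            d = dirs[idx]
            px = coords[parent, 0]
            py = coords[parent, 1]
            pz = coords[parent, 2]
            placed = False
            for _ in range(seg_attempts):
                total_attempts += 1
                k = np.random.randint(0, nb)
                bx = bonds[k, 0]
                by = bonds[k, 1]
                bz = bonds[k, 2]
                if flip_prob > 0.0 and bx * d < 0 and np.random.random() < flip_prob:
                    bx = -bx
                iy = py + by
                cy = py + 2 * by
                iz = pz + bz
                cz = pz + 2 * bz
                if iy < lo_y or iy > lo_y + extent or cy < lo_y or cy > lo_y + extent:
                    continue
                if iz < lo_z or iz > lo_z + extent or cz < lo_z or cz > lo_z + extent:
                    continue
                ix = px + bx
                cx = px + 2 * bx
                if grid[ix % L, iy % L, iz % L] != 0:
                    continue
                if grid[cx % L, cy % L, cz % L] != 0:
                    continue
                coords[inter, 0] = ix
                coords[inter, 1] = iy
                coords[inter, 2] = iz
                coords[child, 0] = cx
                coords[child, 1] = cy
                coords[child, 2] = cz
                _grid_update(grid, L, ix, iy, iz, 1)
                _grid_update(grid, L, cx, cy, cz, 1)
                placed = True
                break
            if placed:
                idx += 1
                streak = 0
                continue
            streak += 1
            depth = 2 ** min(streak, 8)
            if depth > idx:
                depth = idx
            budget -= depth if depth > 0 else 1
            if idx == 0 or budget < 0:
                ok = False
                break
            for _ in range(depth):
                idx -= 1
                ii = segments[idx, 1]
                cc = segments[idx, 2]
                _grid_update(grid, L, coords[ii, 0], coords[ii, 1], coords[ii, 2], -1)
                _grid_update(grid, L, coords[cc, 0], coords[cc, 1], coords[cc, 2], -1)
        if ok:
            return True, restart, total_attempts
        # undo everything placed in this restart
        for s in range(idx):
            ii = segments[s, 1]
            cc = segments[s, 2]
            _grid_update(grid, L, coords[ii, 0], coords[ii, 1], coords[ii, 2], -1)
            _grid_update(grid, L, coords[cc, 0], coords[cc, 1], coords[cc, 2], -1)
        _grid_update(grid, L, coords[0, 0], coords[0, 1], coords[0, 2], -1)
        _grid_update(grid, L, coords[1, 0], coords[1, 1], coords[1, 2], -1)
    return False, max_restarts, total_attempts


@njit(cache=True)
def run_bead_jumps(
    coords,        # int64[n, 3] unwrapped, modified in place
    grid,          # uint8[L, L, L] blocked counts, modified in place
    L,             # int box edge
    indptr,        # int64[n+1] CSR adjacency
    indices,       # int64[m]
    bond_ok,       # bool[7, 7, 7], index comp+3
    bond_class,    # int8[7, 7, 7]
    energies,      # float64[6] per-class bond energy (k_B T)
    moves,         # int64[n_moves, 3]; every move must have Chebyshev norm 1
    n_attempts,    # int64
    seed,          # uint32-ish int
    athermal,      # bool: skip energy evaluation entirely
):
    """Perform ``n_attempts`` single-unit jump attempts; return accept count.

    Each attempt: draw a unit and a move uniformly; reject unless every
    incident bond stays in the allowed set and the target site is free of
    other units (its blocked count is exactly the mover's own
    contribution, valid because all moves have Chebyshev norm 1);
    otherwise apply the Metropolis rule on the bond-energy change.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    n_moves = moves.shape[0]
    accepted = 0
    for _ in range(n_attempts):
        u = np.random.randint(0, n)
        m = np.random.randint(0, n_moves)
        ox = coords[u, 0]
        oy = coords[u, 1]
        oz = coords[u, 2]
        nx = ox + moves[m, 0]
        ny = oy + moves[m, 1]
        nz = oz + moves[m, 2]

        # bond-set check for every neighbour
        ok = True
        for e in range(indptr[u], indptr[u + 1]):
            v = indices[e]
            bx = coords[v, 0] - nx
            by = coords[v, 1] - ny
            bz = coords[v, 2] - nz
            if bx < -3 or bx > 3 or by < -3 or by > 3 or bz < -3 or bz > 3:
                ok = False
                break
            if not bond_ok[bx + 3, by + 3, bz + 3]:
                ok = False
                break
        if not ok:
            continue

        # excluded volume: the target cell counts the mover itself once
        wx = nx % L
        wy = ny % L
        wz = nz % L
        if grid[wx, wy, wz] != 1:
            continue

        if not athermal:
            dE = 0.0
            for e in range(indptr[u], indptr[u + 1]):
                v = indices[e]
                obx = coords[v, 0] - ox
                oby = coords[v, 1] - oy
                obz = coords[v, 2] - oz
                nbx = coords[v, 0] - nx
                nby = coords[v, 1] - ny
                nbz = coords[v, 2] - nz
                dE += energies[bond_class[nbx + 3, nby + 3, nbz + 3]]
                dE -= energies[bond_class[obx + 3, oby + 3, obz + 3]]
            if dE > 0.0 and np.random.random() >= np.exp(-dE):
                continue

        # accept: move the 27-cell blocked neighbourhood
        owx = ox % L
        owy = oy % L
        owz = oz % L
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                for dz in range(-1, 2):
                    grid[(owx + dx) % L, (owy + dy) % L, (owz + dz) % L] -= 1
                    grid[(wx + dx) % L, (wy + dy) % L, (wz + dz) % L] += 1
        coords[u, 0] = nx
        coords[u, 1] = ny
        coords[u, 2] = nz
        accepted += 1
    return accepted


@njit(cache=True)
def any_intermolecular_overlap(a, b, dx, dy, dz):
    """True iff any unit of ``a`` and any unit of ``b + (dx,dy,dz)`` come
    within Chebyshev distance < 2 (continuum displaced frame)."""
    na = a.shape[0]
    nb = b.shape[0]
    for i in range(na):
        ax = a[i, 0]
        ay = a[i, 1]
        az = a[i, 2]
        for j in range(nb):
            ddx = ax - b[j, 0] - dx
            if ddx < -2.0 or ddx > 2.0:
                continue
            ddy = ay - b[j, 1] - dy
            if ddy < -2.0 or ddy > 2.0:
                continue
            ddz = az - b[j, 2] - dz
            if ddz > -2.0 and ddz < 2.0:
                return True
    return False


@njit(cache=True, inline="always")
def _pair_w(r2, c0, c1, c2, rcut2):
    if r2 > rcut2:
        return 0.0
    return np.exp(c0 + c1 * r2 + c2 * r2 * r2)


@njit(cache=True)
def run_pointlike_kernel(
    pos,            # float64[n, 3] in [0, L), modified in place
    L,              # float box edge
    c0, c1, c2,     # potential coefficients: w(r) = exp(c0 + c1 r² + c2 r⁴)
    rcut2,          # squared cutoff; w = 0 beyond
    n_moves,        # total displacement attempts
    max_disp,       # maximal jump magnitude (uniform in [0, max_disp])
    seed,
    sample_every,   # store a snapshot every this many attempts
    samples,        # float64[n_samples, n, 3] output buffer
    cube_moves,     # bool: per-coordinate cube displacement instead of sphere
):
    """Metropolis MC for point particles with the fitted pair potential.

    Returns (accepted, n_stored, final_total_energy_estimate).  Energy is
    tracked incrementally from an initial full pairwise sum.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    half = L / 2.0

    # initial total energy
    etot = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            ddx = pos[i, 0] - pos[j, 0]
            if ddx > half:
                ddx -= L
            elif ddx < -half:
                ddx += L
            ddy = pos[i, 1] - pos[j, 1]
            if ddy > half:
                ddy -= L
            elif ddy < -half:
                ddy += L
            ddz = pos[i, 2] - pos[j, 2]
            if ddz > half:
                ddz -= L
            elif ddz < -half:
                ddz += L
            etot += _pair_w(ddx * ddx + ddy * ddy + ddz * ddz, c0, c1, c2, rcut2)

    accepted = 0
    stored = 0
    max_store = samples.shape[0]
    for step in range(n_moves):
        i = np.random.randint(0, n)
        if cube_moves:
            mx = (np.random.random() * 2.0 - 1.0) * max_disp
            my = (np.random.random() * 2.0 - 1.0) * max_disp
            mz = (np.random.random() * 2.0 - 1.0) * max_disp
        else:
            # uniform direction on the sphere, magnitude uniform in [0, max_disp]
            z = 1.0 - 2.0 * np.random.random()
            phi = 2.0 * np.pi * np.random.random()
            s = np.sqrt(max(0.0, 1.0 - z * z))
            r = max_disp * np.random.random()
            mx = r * s * np.cos(phi)
            my = r * s * np.sin(phi)
            mz = r * z
        nx = (pos[i, 0] + mx) % L
        ny = (pos[i, 1] + my) % L
        nz = (pos[i, 2] + mz) % L

        dE = 0.0
        for j in range(n):
            if j == i:
                continue
            # old
            ddx = pos[i, 0] - pos[j, 0]
            if ddx > half:
                ddx -= L
            elif ddx < -half:
                ddx += L
            ddy = pos[i, 1] - pos[j, 1]
            if ddy > half:
                ddy -= L
            elif ddy < -half:
                ddy += L
            ddz = pos[i, 2] - pos[j, 2]
            if ddz > half:
                ddz -= L
            elif ddz < -half:
                ddz += L
            dE -= _pair_w(ddx * ddx + ddy * ddy + ddz * ddz, c0, c1, c2, rcut2)
            # new
            ddx = nx - pos[j, 0]
            if ddx > half:
                ddx -= L
            elif ddx < -half:
                ddx += L
            ddy = ny - pos[j, 1]
            if ddy > half:
                ddy -= L
            elif ddy < -half:
                ddy += L
            ddz = nz - pos[j, 2]
            if ddz > half:
                ddz -= L
            elif ddz < -half:
                ddz += L
            dE += _pair_w(ddx * ddx + ddy * ddy + ddz * ddz, c0, c1, c2, rcut2)

        if dE <= 0.0 or np.random.random() < np.exp(-dE):
            pos[i, 0] = nx
            pos[i, 1] = ny
            pos[i, 2] = nz
            etot += dE
            accepted += 1

        if (step + 1) % sample_every == 0 and stored < max_store:
            for a in range(n):
                samples[stored, a, 0] = pos[a, 0]
                samples[stored, a, 1] = pos[a, 1]
                samples[stored, a, 2] = pos[a, 2]
            stored += 1

    return accepted, stored, etot
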