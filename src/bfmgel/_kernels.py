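"""Numba kernels for the lattice Monte Carlo engine.

All kernels operate on flat/contiguous numpy arrays prepared by
``bfmgel.lattice.SimContext``.  Positions are wrapped integer triples in
``[0, L)``; every monomer occupies the 2x2x2 site block anchored at its
position.  Occupancy and PEG-centre grids are flat ``uint8`` arrays of
length ``L**3`` indexed by ``(x*L + y)*L + z``.

Rigid molecules (heparin rods) never move monomer-by-monomer: when one of
their monomers is drawn, a whole-molecule move is attempted with
probability ``1/size`` (half unit translations, half 90-degree rotations
about the rod's first monomer), so each rod makes on average one rigid
move attempt per Monte Carlo step while keeping its exact shape.

The random stream is an inline xorshift64 generator whose state is
threaded through the helpers as a scalar so it stays in a register
(numba's ``np.random`` dispatch, or any array-held state, is far too slow
for the innermost loop); each kernel call is seeded via splitmix64.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mc_kernel", "single_move_kernel"]


@njit(inline="always")
def _xs64(x):
    x ^= x << np.uint64(13)
    x ^= x >> np.uint64(7)
    x ^= x << np.uint64(17)
    return x


@njit(inline="always")
def _bounded(word32, n):
    # multiply-shift reduction of a 32-bit word; bias O(n / 2^32)
    return np.int64((word32 * np.uint64(n)) >> np.uint64(32))


@njit(inline="always")
def _to_float(x):
    return np.float64(x >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(inline="always")
def _seed_state(seed):
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x106689D45497FDB5)
    return z


@njit(inline="always")
def _sidx(x, y, z, L):
    return (x * L + y) * L + z


@njit(inline="always")
def _fold(c, L):
    # valid for offsets up to +-(L-1) outside the box
    if c >= L:
        return c - L
    if c < 0:
        return c + L
    return c


@njit(inline="always")
def _mi(d, L):
    h = L >> 1
    if d > h:
        return d - L
    if d < -h:
        return d + L
    return d


@njit(inline="always")
def _bond_ok(dx, dy, dz, allowed):
    if dx < -3 or dx > 3 or dy < -3 or dy > 3 or dz < -3 or dz > 3:
        return False
    return allowed[dx + 3, dy + 3, dz + 3] == 1


@njit(inline="always")
def _block_write(grid, x, y, z, L, val):
    x1 = x + 1
    if x1 == L:
        x1 = 0
    y1 = y + 1
    if y1 == L:
        y1 = 0
    z1 = z + 1
    if z1 == L:
        z1 = 0
    grid[_sidx(x, y, z, L)] = val
    grid[_sidx(x, y, z1, L)] = val
    grid[_sidx(x, y1, z, L)] = val
    grid[_sidx(x, y1, z1, L)] = val
    grid[_sidx(x1, y, z, L)] = val
    grid[_sidx(x1, y, z1, L)] = val
    grid[_sidx(x1, y1, z, L)] = val
    grid[_sidx(x1, y1, z1, L)] = val


@njit(inline="always")
def _block_free(occ, x, y, z, L):
    x1 = x + 1
    if x1 == L:
        x1 = 0
    y1 = y + 1
    if y1 == L:
        y1 = 0
    z1 = z + 1
    if z1 == L:
        z1 = 0
    if occ[_sidx(x, y, z, L)] != 0:
        return False
    if occ[_sidx(x, y, z1, L)] != 0:
        return False
    if occ[_sidx(x, y1, z, L)] != 0:
        return False
    if occ[_sidx(x, y1, z1, L)] != 0:
        return False
    if occ[_sidx(x1, y, z, L)] != 0:
        return False
    if occ[_sidx(x1, y, z1, L)] != 0:
        return False
    if occ[_sidx(x1, y1, z, L)] != 0:
        return False
    if occ[_sidx(x1, y1, z1, L)] != 0:
        return False
    return True


@njit(inline="always")
def _plane_sites(axis, a, b0, b1, c0, c1, L):
    """Site indices of the 2x2 plane at coordinate ``a`` along ``axis``.

    For axis 0 the plane spans (y, z) = (b, c); axis 1 spans (x, z);
    axis 2 spans (x, y).
    """
    if axis == 0:
        return (_sidx(a, b0, c0, L), _sidx(a, b0, c1, L),
                _sidx(a, b1, c0, L), _sidx(a, b1, c1, L))
    elif axis == 1:
        return (_sidx(b0, a, c0, L), _sidx(b0, a, c1, L),
                _sidx(b1, a, c0, L), _sidx(b1, a, c1, L))
    else:
        return (_sidx(b0, c0, a, L), _sidx(b0, c1, a, L),
                _sidx(b1, c0, a, L), _sidx(b1, c1, a, L))


@njit(inline="always")
def _flex_move(pos, species, nbr, ncnt, occ, pegc, L, m, axis, sgn,
               use_energy, eps_neg, add_off, rem_off, exptab, allowed, rs):
    """Attempt a single-monomer unit-step move.

    Returns ``(accepted, rs)`` with the advanced RNG state."""
    x = pos[m, 0]
    y = pos[m, 1]
    z = pos[m, 2]
    if axis == 0:
        pa = x
    elif axis == 1:
        pa = y
    else:
        pa = z

    # claimed 2x2 plane of the target block
    if sgn > 0:
        cc = _fold(pa + 2, L)
    else:
        cc = _fold(pa - 1, L)
    if axis == 0:
        b0 = y
        c0 = z
    elif axis == 1:
        b0 = x
        c0 = z
    else:
        b0 = x
        c0 = y
    b1 = b0 + 1
    if b1 == L:
        b1 = 0
    c1 = c0 + 1
    if c1 == L:
        c1 = 0
    s0, s1, s2, s3 = _plane_sites(axis, cc, b0, b1, c0, c1, L)
    if occ[s0] != 0 or occ[s1] != 0 or occ[s2] != 0 or occ[s3] != 0:
        return False, rs

    na = _fold(pa + sgn, L)
    if axis == 0:
        nx, ny, nz = na, y, z
    elif axis == 1:
        nx, ny, nz = x, na, z
    else:
        nx, ny, nz = x, y, na

    # all incident bonds must stay in the allowed set
    for t in range(ncnt[m]):
        j = nbr[m, t]
        dx = _mi(pos[j, 0] - nx, L)
        dy = _mi(pos[j, 1] - ny, L)
        dz = _mi(pos[j, 2] - nz, L)
        if not _bond_ok(dx, dy, dz, allowed):
            return False, rs

    # Metropolis on the PEG-PEG contact energy
    if use_energy and species[m] == 0:
        d6 = axis * 2 + (0 if sgn > 0 else 1)
        nadd = 0
        nrem = 0
        for t in range(add_off.shape[1]):
            ox = _fold(x + add_off[d6, t, 0], L)
            oy = _fold(y + add_off[d6, t, 1], L)
            oz = _fold(z + add_off[d6, t, 2], L)
            nadd += pegc[_sidx(ox, oy, oz, L)]
        for t in range(rem_off.shape[1]):
            ox = _fold(x + rem_off[d6, t, 0], L)
            oy = _fold(y + rem_off[d6, t, 1], L)
            oz = _fold(z + rem_off[d6, t, 2], L)
            nrem += pegc[_sidx(ox, oy, oz, L)]
        du = nadd - nrem
        if eps_neg:
            bad = -du  # attractive: losing contacts costs energy
        else:
            bad = du
        if bad > 0:
            rs = _xs64(rs)
            if _to_float(rs) >= exptab[bad]:
                return False, rs

    # commit: vacated plane of the old block
    if sgn > 0:
        vc = pa
    else:
        vc = _fold(pa + 1, L)
    v0, v1, v2, v3 = _plane_sites(axis, vc, b0, b1, c0, c1, L)
    occ[v0] = 0
    occ[v1] = 0
    occ[v2] = 0
    occ[v3] = 0
    occ[s0] = 1
    occ[s1] = 1
    occ[s2] = 1
    occ[s3] = 1
    if use_energy and species[m] == 0:
        pegc[_sidx(x, y, z, L)] = 0
        pegc[_sidx(nx, ny, nz, L)] = 1
    pos[m, 0] = nx
    pos[m, 1] = ny
    pos[m, 2] = nz
    return True, rs


@njit
def _rigid_move(pos, mol_lo, mol_hi, nbr, ncnt, occ, L, m, axis, sgn,
                allowed):
    """Attempt a rigid-body unit translation of monomer ``m``'s molecule."""
    lo = mol_lo[m]
    hi = mol_hi[m]
    dx = sgn if axis == 0 else 0
    dy = sgn if axis == 1 else 0
    dz = sgn if axis == 2 else 0

    # clear own blocks so intra-molecular overlap does not self-reject
    for i in range(lo, hi):
        _block_write(occ, pos[i, 0], pos[i, 1], pos[i, 2], L, 0)

    ok = True
    for i in range(lo, hi):
        nx = _fold(pos[i, 0] + dx, L)
        ny = _fold(pos[i, 1] + dy, L)
        nz = _fold(pos[i, 2] + dz, L)
        if not _block_free(occ, nx, ny, nz, L):
            ok = False
            break

    if ok:
        # bonds leaving the molecule (crosslinks to starPEG) must stay legal
        for i in range(lo, hi):
            nx = _fold(pos[i, 0] + dx, L)
            ny = _fold(pos[i, 1] + dy, L)
            nz = _fold(pos[i, 2] + dz, L)
            for t in range(ncnt[i]):
                j = nbr[i, t]
                if j < lo or j >= hi:
                    bx = _mi(pos[j, 0] - nx, L)
                    by = _mi(pos[j, 1] - ny, L)
                    bz = _mi(pos[j, 2] - nz, L)
                    if not _bond_ok(bx, by, bz, allowed):
                        ok = False
                        break
            if not ok:
                break

    if ok:
        for i in range(lo, hi):
            pos[i, 0] = _fold(pos[i, 0] + dx, L)
            pos[i, 1] = _fold(pos[i, 1] + dy, L)
            pos[i, 2] = _fold(pos[i, 2] + dz, L)
    for i in range(lo, hi):
        _block_write(occ, pos[i, 0], pos[i, 1], pos[i, 2], L, 1)
    return ok


@njit
def _rigid_rotate(pos, mol_lo, mol_hi, nbr, ncnt, occ, L, m, rot, allowed,
                  newpos):
    """Attempt a 90-degree rigid rotation of monomer ``m``'s molecule
    about its first monomer (anchor pivot; exactly invertible, so the
    proposal set is symmetric)."""
    lo = mol_lo[m]
    hi = mol_hi[m]
    x0 = pos[lo, 0]
    y0 = pos[lo, 1]
    z0 = pos[lo, 2]
    for i in range(lo, hi):
        _block_write(occ, pos[i, 0], pos[i, 1], pos[i, 2], L, 0)
    ok = True
    for i in range(lo, hi):
        dx = _mi(pos[i, 0] - x0, L)
        dy = _mi(pos[i, 1] - y0, L)
        dz = _mi(pos[i, 2] - z0, L)
        nx = _fold(x0 + rot[0, 0] * dx + rot[0, 1] * dy + rot[0, 2] * dz, L)
        ny = _fold(y0 + rot[1, 0] * dx + rot[1, 1] * dy + rot[1, 2] * dz, L)
        nz = _fold(z0 + rot[2, 0] * dx + rot[2, 1] * dy + rot[2, 2] * dz, L)
        k = i - lo
        newpos[k, 0] = nx
        newpos[k, 1] = ny
        newpos[k, 2] = nz
        if not _block_free(occ, nx, ny, nz, L):
            ok = False
            break
    if ok:
        for i in range(lo, hi):
            k = i - lo
            for t in range(ncnt[i]):
                j = nbr[i, t]
                if j < lo or j >= hi:
                    bx = _mi(pos[j, 0] - newpos[k, 0], L)
                    by = _mi(pos[j, 1] - newpos[k, 1], L)
                    bz = _mi(pos[j, 2] - newpos[k, 2], L)
                    if not _bond_ok(bx, by, bz, allowed):
                        ok = False
                        break
            if not ok:
                break
    if ok:
        for i in range(lo, hi):
            k = i - lo
            pos[i, 0] = newpos[k, 0]
            pos[i, 1] = newpos[k, 1]
            pos[i, 2] = newpos[k, 2]
    for i in range(lo, hi):
        _block_write(occ, pos[i, 0], pos[i, 1], pos[i, 2], L, 1)
    return ok


@njit
def _try_react(m, pos, hq, hid, nbr, ncnt, consumed, scan_off, L,
               ev_peg, ev_hep, ev_mcs, n_ev, tnow, cand, rs, p_react):
    """Scan the heparin reactive-site grid around terminus ``m``; form at
    most one permanent crosslink (uniform tie-break).  With probability
    ``1 - p_react`` the collision is unreactive (activation barrier),
    which sets the reaction-vs-diffusion control regime.  Returns
    ``(n_ev, rs)``."""
    x = pos[m, 0]
    y = pos[m, 1]
    z = pos[m, 2]
    ncand = 0
    for t in range(scan_off.shape[0]):
        ox = _fold(x + scan_off[t, 0], L)
        oy = _fold(y + scan_off[t, 1], L)
        oz = _fold(z + scan_off[t, 2], L)
        s = _sidx(ox, oy, oz, L)
        if hq[s] != 0:
            cand[ncand] = s
            ncand += 1
    if ncand == 0:
        return n_ev, rs
    if p_react < 1.0:
        rs = _xs64(rs)
        if _to_float(rs) >= p_react:
            return n_ev, rs
    if ncand == 1:
        s = cand[0]
    else:
        rs = _xs64(rs)
        s = cand[_bounded(rs >> np.uint64(32), ncand)]
    j = hid[s] - 1
    # permanent bond: append to both adjacency lists
    nbr[m, ncnt[m]] = j
    ncnt[m] += 1
    nbr[j, ncnt[j]] = m
    ncnt[j] += 1
    consumed[m] = 1
    consumed[j] = 1
    hq[s] = 0
    hid[s] = 0
    ev_peg[n_ev] = m
    ev_hep[n_ev] = j
    ev_mcs[n_ev] = tnow
    return n_ev + 1, rs


@njit(cache=True)
def mc_kernel(pos, species, rigid, mol_lo, mol_hi, nbr, ncnt,
              occ, pegc, L, n_attempts,
              use_energy, eps_neg, exptab, add_off, rem_off, allowed,
              do_react, reactive, consumed, hq, hid, scan_off, term_list,
              sweep_every, target_bonds, n_bonds, ev_peg, ev_hep, ev_mcs,
              n_ev, attempts_base, p_react, rot_mats, max_mol, seed):
    """Main Monte Carlo loop.

    Performs ``n_attempts`` attempted moves.  With ``do_react`` the kernel
    additionally forms permanent crosslink bonds by direct collision:
    event-driven after every accepted move of an unconsumed starPEG
    terminus, plus a periodic safety sweep over all unconsumed termini
    (which also catches collisions created by rigid heparin motion).

    Returns ``(attempts_done, n_accepted, n_ev, n_bonds)``; stops early as
    soon as ``n_bonds`` reaches ``target_bonds``.
    """
    rs = _seed_state(seed)
    N = pos.shape[0]
    cand = np.empty(scan_off.shape[0], dtype=np.int64)
    newpos = np.empty((max_mol, 3), dtype=np.int64)
    n_acc = 0

    if do_react and n_bonds < target_bonds:
        # initial sweep: partners may already be in collision range
        tnow = attempts_base / N
        for k in range(term_list.shape[0]):
            tm = term_list[k]
            if consumed[tm] != 0:
                continue
            new_ev, rs = _try_react(tm, pos, hq, hid, nbr, ncnt, consumed,
                                    scan_off, L, ev_peg, ev_hep, ev_mcs,
                                    n_ev, tnow, cand, rs, p_react)
            if new_ev > n_ev:
                n_ev = new_ev
                n_bonds += 1
                if n_bonds >= target_bonds:
                    return 0, n_acc, n_ev, n_bonds

    for a in range(n_attempts):
        rs = _xs64(rs)
        m = _bounded(rs >> np.uint64(32), N)
        d6 = _bounded(rs & np.uint64(0xFFFFFFFF), 6)
        axis = d6 >> 1
        sgn = 1 if (d6 & 1) == 0 else -1

        if rigid[m] != 0:
            msize = mol_hi[m] - mol_lo[m]
            rs = _xs64(rs)
            if _to_float(rs) * msize < 1.0:
                if do_react:
                    # lift the rod's reactive sites off the grid; they are
                    # rewritten below at whichever positions the move left
                    for i in range(mol_lo[m], mol_hi[m]):
                        if reactive[i] != 0 and consumed[i] == 0:
                            s = _sidx(pos[i, 0], pos[i, 1], pos[i, 2], L)
                            hq[s] = 0
                            hid[s] = 0
                rs = _xs64(rs)
                if _to_float(rs) < 0.5:
                    acc = _rigid_move(pos, mol_lo, mol_hi, nbr, ncnt, occ,
                                      L, m, axis, sgn, allowed)
                else:
                    rs = _xs64(rs)
                    r6 = _bounded(rs >> np.uint64(32), rot_mats.shape[0])
                    acc = _rigid_rotate(pos, mol_lo, mol_hi, nbr, ncnt,
                                        occ, L, m, rot_mats[r6], allowed,
                                        newpos)
                if acc:
                    n_acc += 1
                if do_react:
                    for i in range(mol_lo[m], mol_hi[m]):
                        if reactive[i] != 0 and consumed[i] == 0:
                            s = _sidx(pos[i, 0], pos[i, 1], pos[i, 2], L)
                            hq[s] = 1
                            hid[s] = i + 1
        else:
            # single-monomer move, inlined by hand: a helper-function
            # boundary here costs several times the move itself
            acc = False
            x = pos[m, 0]
            y = pos[m, 1]
            z = pos[m, 2]
            if axis == 0:
                pa = x
            elif axis == 1:
                pa = y
            else:
                pa = z
            if sgn > 0:
                cc = _fold(pa + 2, L)
            else:
                cc = _fold(pa - 1, L)
            if axis == 0:
                b0 = y
                c0 = z
            elif axis == 1:
                b0 = x
                c0 = z
            else:
                b0 = x
                c0 = y
            b1 = b0 + 1
            if b1 == L:
                b1 = 0
            c1 = c0 + 1
            if c1 == L:
                c1 = 0
            s0, s1, s2, s3 = _plane_sites(axis, cc, b0, b1, c0, c1, L)
            if occ[s0] == 0 and occ[s1] == 0 and occ[s2] == 0 \
                    and occ[s3] == 0:
                na = _fold(pa + sgn, L)
                if axis == 0:
                    nx, ny, nz = na, y, z
                elif axis == 1:
                    nx, ny, nz = x, na, z
                else:
                    nx, ny, nz = x, y, na
                ok = True
                for t in range(ncnt[m]):
                    j = nbr[m, t]
                    dx = _mi(pos[j, 0] - nx, L)
                    dy = _mi(pos[j, 1] - ny, L)
                    dz = _mi(pos[j, 2] - nz, L)
                    if not _bond_ok(dx, dy, dz, allowed):
                        ok = False
                        break
                if ok and use_energy and species[m] == 0:
                    nadd = 0
                    nrem = 0
                    for t in range(add_off.shape[1]):
                        ox = _fold(x + add_off[d6, t, 0], L)
                        oy = _fold(y + add_off[d6, t, 1], L)
                        oz = _fold(z + add_off[d6, t, 2], L)
                        nadd += pegc[_sidx(ox, oy, oz, L)]
                    for t in range(rem_off.shape[1]):
                        ox = _fold(x + rem_off[d6, t, 0], L)
                        oy = _fold(y + rem_off[d6, t, 1], L)
                        oz = _fold(z + rem_off[d6, t, 2], L)
                        nrem += pegc[_sidx(ox, oy, oz, L)]
                    du = nadd - nrem
                    bad = -du if eps_neg else du
                    if bad > 0:
                        rs = _xs64(rs)
                        if _to_float(rs) >= exptab[bad]:
                            ok = False
                if ok:
                    if sgn > 0:
                        vc = pa
                    else:
                        vc = _fold(pa + 1, L)
                    v0, v1, v2, v3 = _plane_sites(axis, vc, b0, b1, c0,
                                                  c1, L)
                    occ[v0] = 0
                    occ[v1] = 0
                    occ[v2] = 0
                    occ[v3] = 0
                    occ[s0] = 1
                    occ[s1] = 1
                    occ[s2] = 1
                    occ[s3] = 1
                    if use_energy and species[m] == 0:
                        pegc[_sidx(x, y, z, L)] = 0
                        pegc[_sidx(nx, ny, nz, L)] = 1
                    pos[m, 0] = nx
                    pos[m, 1] = ny
                    pos[m, 2] = nz
                    acc = True
            if acc:
                n_acc += 1
                if do_react and reactive[m] != 0 and consumed[m] == 0 \
                        and species[m] == 0:
                    tnow = (attempts_base + a) / N
                    new_ev, rs = _try_react(m, pos, hq, hid, nbr, ncnt,
                                            consumed, scan_off, L, ev_peg,
                                            ev_hep, ev_mcs, n_ev, tnow,
                                            cand, rs, p_react)
                    if new_ev > n_ev:
                        n_ev = new_ev
                        n_bonds += 1
                        if n_bonds >= target_bonds:
                            return a + 1, n_acc, n_ev, n_bonds

        if do_react and sweep_every > 0 \
                and (attempts_base + a + 1) % sweep_every == 0:
            tnow = (attempts_base + a + 1) / N
            for k in range(term_list.shape[0]):
                tm = term_list[k]
                if consumed[tm] != 0:
                    continue
                new_ev, rs = _try_react(tm, pos, hq, hid, nbr, ncnt,
                                        consumed, scan_off, L, ev_peg,
                                        ev_hep, ev_mcs, n_ev, tnow, cand,
                                        rs, p_react)
                if new_ev > n_ev:
                    n_ev = new_ev
                    n_bonds += 1
                    if n_bonds >= target_bonds:
                        return a + 1, n_acc, n_ev, n_bonds

    return n_attempts, n_acc, n_ev, n_bonds


@njit(cache=True)
def single_move_kernel(pos, species, rigid, mol_lo, mol_hi, nbr, ncnt,
                       occ, pegc, L, m, axis, sgn,
                       use_energy, eps_neg, exptab, add_off, rem_off,
                       allowed, seed):
    """Attempt one prescribed move (used by ``attempt_move``).

    Rigid monomers translate their whole molecule along the requested
    direction."""
    rs = _seed_state(seed)
    if rigid[m] != 0:
        return _rigid_move(pos, mol_lo, mol_hi, nbr, ncnt, occ, L, m,
                           axis, sgn, allowed)
    acc, _rs = _flex_move(pos, species, nbr, ncnt, occ, pegc, L, m, axis,
                          sgn, use_energy, eps_neg, add_off, rem_off,
                          exptab, allowed, rs)
    return acc
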