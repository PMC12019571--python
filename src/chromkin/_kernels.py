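"""Numba kernels for the production integrator.

The public functions here mirror the reference implementations in
:mod:`chromkin.model_core` / :mod:`chromkin.kinetics`; the unit tests assert
agreement between the two paths.  The production ``run_kernel`` works in
float32 internally (positions, forces, noise) -- thermal noise dwarfs the
rounding error by many orders of magnitude -- while the reference functions
(`compute_forces`, `total_energy`, `exchange_delta_e`) stay in float64.

Randomness comes from a hand-rolled PCG32 generator so that one integer seed
plus a stream id gives fully reproducible, independent sub-streams for the
motion noise, the exchange moves and the reaction moves (a cadence change in
one process then cannot shift the draws of another).
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
U32 = np.uint32
F32 = np.float32
_PCG_MULT = U64(6364136223846793005)

# counter slots written by the run kernel
C_EXCH_PROP = 0
C_EXCH_TRIVIAL = 1
C_EXCH_ACC = 2
C_EXCH_REJ = 3
C_EXCH_NOOP = 4
C_REACT_MOVES = 5
C_REACT_TO_E = 6
C_REACT_TO_H = 7
C_CAP_HITS = 8
C_REBUILDS = 9
N_COUNTERS = 10

# kernel exit codes
OK = 0
ERR_OVEREXTENSION = 1
ERR_PAIR_OVERFLOW = 2
ERR_NONFINITE = 3


# ------------------------------------------------------------------- RNG


@njit(cache=True, inline="always")
def _pcg_next(s):
    old = s[0]
    s[0] = old * _PCG_MULT + s[1]
    xorshifted = U32(((old >> U64(18)) ^ old) >> U64(27))
    rot = U32(old >> U64(59))
    return U32((xorshifted >> rot) | (xorshifted << ((U32(0) - rot) & U32(31))))


@njit(cache=True, inline="always")
def _pcg_init(s, seed, stream):
    s[1] = (U64(stream) << U64(1)) | U64(1)
    s[0] = U64(0)
    _pcg_next(s)
    s[0] = s[0] + U64(seed)
    _pcg_next(s)


@njit(cache=True, inline="always")
def _uniform(s):
    # (0, 1), never exactly 0 so log() is safe
    return (np.float64(_pcg_next(s)) + 0.5) * (1.0 / 4294967296.0)


@njit(cache=True, inline="always")
def _randint(s, n):
    k = np.int64(_uniform(s) * n)
    if k >= n:
        k = n - 1
    return k


@njit(cache=True, fastmath=True)
def _fill_normals32(s, out):
    """Marsaglia polar method, two float32 normals per accepted pair."""
    m = out.shape[0]
    i = 0
    while i < m:
        v1 = 2.0 * _uniform(s) - 1.0
        v2 = 2.0 * _uniform(s) - 1.0
        q = v1 * v1 + v2 * v2
        if q >= 1.0 or q == 0.0:
            continue
        fac = np.sqrt(-2.0 * np.log(q) / q)
        out[i] = F32(v1 * fac)
        i += 1
        if i < m:
            out[i] = F32(v2 * fac)
            i += 1


# ------------------------------------------------- neighbor list builders


@njit(cache=True, fastmath=True)
def build_pairs(pos, rlist2, box, periodic, pi, pj):
    """Brute-force Verlet pair build (dtype-generic); returns the pair count
    (may exceed capacity, in which case the caller grows the buffers and
    retries).  Chain-bonded pairs (j == i+1) are excluded: the bond loop
    handles them."""
    n = pos.shape[0]
    cap = pi.shape[0]
    rlist = np.sqrt(rlist2)
    m = 0
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 2, n):
            d0 = pos[j, 0] - xi
            if periodic:
                d0 -= box * np.rint(d0 / box)
            if d0 > rlist or d0 < -rlist:
                continue
            d1 = pos[j, 1] - yi
            d2 = pos[j, 2] - zi
            if periodic:
                d1 -= box * np.rint(d1 / box)
                d2 -= box * np.rint(d2 / box)
            if d0 * d0 + d1 * d1 + d2 * d2 < rlist2:
                if m < cap:
                    pi[m] = i
                    pj[m] = j
                m += 1
    return m


@njit(cache=True, fastmath=True)
def build_pairs_cells(pos, rlist2, box, periodic, pi, pj):
    """Cell-assisted Verlet build; falls back to the brute scan for small
    systems or boxes below 3 cells per edge."""
    n = pos.shape[0]
    rlist = np.sqrt(rlist2)
    nc = int(box / rlist)
    if nc < 3 or n < 64:
        return build_pairs(pos, rlist2, box, periodic, pi, pj)
    inv = nc / box
    head = np.full(nc * nc * nc, -1, dtype=np.int32)
    nxt = np.empty(n, dtype=np.int32)
    cx = np.empty(n, dtype=np.int32)
    cy = np.empty(n, dtype=np.int32)
    cz = np.empty(n, dtype=np.int32)
    for i in range(n):
        a = int(pos[i, 0] * inv)
        b = int(pos[i, 1] * inv)
        c = int(pos[i, 2] * inv)
        if a < 0:
            a = 0
        elif a >= nc:
            a = nc - 1
        if b < 0:
            b = 0
        elif b >= nc:
            b = nc - 1
        if c < 0:
            c = 0
        elif c >= nc:
            c = nc - 1
        cx[i] = a
        cy[i] = b
        cz[i] = c
        cell = (a * nc + b) * nc + c
        nxt[i] = head[cell]
        head[cell] = i
    cap = pi.shape[0]
    m = 0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for da in range(-1, 2):
            a = cx[i] + da
            if periodic:
                a = a % nc
            elif a < 0 or a >= nc:
                continue
            for db in range(-1, 2):
                b = cy[i] + db
                if periodic:
                    b = b % nc
                elif b < 0 or b >= nc:
                    continue
                for dc in range(-1, 2):
                    c = cz[i] + dc
                    if periodic:
                        c = c % nc
                    elif c < 0 or c >= nc:
                        continue
                    j = head[(a * nc + b) * nc + c]
                    while j >= 0:
                        if j > i + 1:
                            d0 = pos[j, 0] - xi
                            d1 = pos[j, 1] - yi
                            d2 = pos[j, 2] - zi
                            if periodic:
                                d0 -= box * np.rint(d0 / box)
                                d1 -= box * np.rint(d1 / box)
                                d2 -= box * np.rint(d2 / box)
                            if d0 * d0 + d1 * d1 + d2 * d2 < rlist2:
                                if m < cap:
                                    pi[m] = i
                                    pj[m] = j
                                m += 1
                        j = nxt[j]
    return m


# ----------------------------------------- float64 reference evaluations


@njit(cache=True, inline="always")
def _dist2(pos, i, j, box, periodic):
    d0 = pos[j, 0] - pos[i, 0]
    d1 = pos[j, 1] - pos[i, 1]
    d2 = pos[j, 2] - pos[i, 2]
    if periodic:
        d0 -= box * np.rint(d0 / box)
        d1 -= box * np.rint(d1 / box)
        d2 -= box * np.rint(d2 / box)
    return d0 * d0 + d1 * d1 + d2 * d2, d0, d1, d2


@njit(cache=True, fastmath=True)
def compute_forces(pos, marks, n_pairs, pi, pj, eps, cut2, fene_K, fene_R0, wca_cut2, box, periodic, forces, force_cap=0.0):
    """Float64 force accumulation over a pair list plus chain bonds.

    Pair-list entries with j == i+1 are skipped (bond loop covers them).
    ``force_cap`` > 0 clips each nonbonded pair force magnitude (soft-core
    regularisation of deep overlaps); the FENE bond force is never clipped
    so bonds cannot creep past their maximum extension.
    """
    n = pos.shape[0]
    cap2 = force_cap * force_cap
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for k in range(n_pairs):
        i = pi[k]
        j = pj[k]
        if j == i + 1:
            continue
        r2, d0, d1, d2 = _dist2(pos, i, j, box, periodic)
        mi = marks[i]
        mj = marks[j]
        c2 = cut2[mi, mj]
        if r2 >= c2 or r2 <= 0.0:
            continue
        e = eps[mi, mj]
        inv2 = 1.0 / r2
        inv6 = inv2 * inv2 * inv2
        f = 24.0 * e * (2.0 * inv6 * inv6 - inv6) * inv2
        if force_cap > 0.0:
            q = f * f * r2
            if q > cap2:
                f = f * force_cap / np.sqrt(q)
        forces[i, 0] -= f * d0
        forces[i, 1] -= f * d1
        forces[i, 2] -= f * d2
        forces[j, 0] += f * d0
        forces[j, 1] += f * d1
        forces[j, 2] += f * d2
    R02 = fene_R0 * fene_R0
    for i in range(n - 1):
        j = i + 1
        r2, d0, d1, d2 = _dist2(pos, i, j, box, periodic)
        if r2 >= R02:
            return ERR_OVEREXTENSION
        f = -fene_K / (1.0 - r2 / R02)
        if 0.0 < r2 < wca_cut2:
            e = eps[marks[i], marks[j]]
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            fw = 24.0 * e * (2.0 * inv6 * inv6 - inv6) * inv2
            if force_cap > 0.0:
                q = fw * fw * r2
                if q > cap2:
                    fw = fw * force_cap / np.sqrt(q)
            f += fw
        forces[i, 0] -= f * d0
        forces[i, 1] -= f * d1
        forces[i, 2] -= f * d2
        forces[j, 0] += f * d0
        forces[j, 1] += f * d1
        forces[j, 2] += f * d2
    return OK


@njit(cache=True, fastmath=True)
def total_energy(pos, marks, eps, cut2, shift, fene_K, fene_R0, wca_cut2, box, periodic):
    """All-pairs (bonded, nonbonded) energy; used for relaxation monitoring."""
    n = pos.shape[0]
    e_b = 0.0
    e_nb = 0.0
    R02 = fene_R0 * fene_R0
    for i in range(n):
        for j in range(i + 1, n):
            r2, _, _, _ = _dist2(pos, i, j, box, periodic)
            mi = marks[i]
            mj = marks[j]
            e = eps[mi, mj]
            if j == i + 1:
                e_b += -0.5 * fene_K * R02 * np.log(1.0 - r2 / R02)
                if 0.0 < r2 < wca_cut2:
                    inv6 = 1.0 / (r2 * r2 * r2)
                    e_b += 4.0 * e * (inv6 * inv6 - inv6) + e
            else:
                c2 = cut2[mi, mj]
                if 0.0 < r2 < c2:
                    inv6 = 1.0 / (r2 * r2 * r2)
                    e_nb += 4.0 * e * (inv6 * inv6 - inv6) - shift[mi, mj]
    return e_b, e_nb


@njit(cache=True, inline="always")
def _bead_pair_energy(r2, bonded, e, c2, sh, wca_cut2):
    """Mark-dependent part of one pair energy (FENE omitted: mark-free)."""
    if 0.0 < r2 < 1e-4:  # overlap floor against inf/NaN at coincident beads
        r2 = 1e-4
    if bonded:
        if 0.0 < r2 < wca_cut2:
            inv6 = 1.0 / (r2 * r2 * r2)
            return 4.0 * e * (inv6 * inv6 - inv6) + e
        return 0.0
    if 0.0 < r2 < c2:
        inv6 = 1.0 / (r2 * r2 * r2)
        return 4.0 * e * (inv6 * inv6 - inv6) - sh
    return 0.0


@njit(cache=True, fastmath=True)
def _bead_energy(pos, marks, i, mark_i, skip, eps, cut2, shift, wca_cut2, box, periodic):
    """Interaction energy of bead ``i`` carrying ``mark_i`` with all beads
    except ``skip`` (the swap partner, whose shared pair term is invariant)."""
    n = pos.shape[0]
    etot = 0.0
    for k in range(n):
        if k == i or k == skip:
            continue
        r2, _, _, _ = _dist2(pos, i, k, box, periodic)
        mk = marks[k]
        bonded = k == i - 1 or k == i + 1
        etot += _bead_pair_energy(
            r2, bonded, eps[mark_i, mk], cut2[mark_i, mk], shift[mark_i, mk], wca_cut2
        )
    return etot


@njit(cache=True, fastmath=True)
def exchange_delta_e(pos, marks, i, j, eps, cut2, shift, wca_cut2, box, periodic):
    """Energy change of swapping the marks of beads i and j, positions fixed."""
    mi = marks[i]
    mj = marks[j]
    before = _bead_energy(pos, marks, i, mi, j, eps, cut2, shift, wca_cut2, box, periodic)
    before += _bead_energy(pos, marks, j, mj, i, eps, cut2, shift, wca_cut2, box, periodic)
    after = _bead_energy(pos, marks, i, mj, j, eps, cut2, shift, wca_cut2, box, periodic)
    after += _bead_energy(pos, marks, j, mi, i, eps, cut2, shift, wca_cut2, box, periodic)
    return after - before


# ----------------------------------------------------- float32 hot path


@njit(cache=True, fastmath=True)
def _forces32(pos, marks, n_pairs, pi, pj, e00, e01, e11, c00, c01, c11, fene_K, fene_R0, wca_cut2, box, periodic, forces, force_cap):
    """Float32 twin of :func:`compute_forces` on a bond-free pair list."""
    n = pos.shape[0]
    zero = F32(0.0)
    cap2 = force_cap * force_cap
    for i in range(n):
        forces[i, 0] = zero
        forces[i, 1] = zero
        forces[i, 2] = zero
    for k in range(n_pairs):
        i = pi[k]
        j = pj[k]
        d0 = pos[j, 0] - pos[i, 0]
        d1 = pos[j, 1] - pos[i, 1]
        d2 = pos[j, 2] - pos[i, 2]
        if periodic:
            d0 -= box * F32(np.rint(d0 / box))
            d1 -= box * F32(np.rint(d1 / box))
            d2 -= box * F32(np.rint(d2 / box))
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        t = marks[i] + marks[j]
        if t == 0:
            e = e00
            c2 = c00
        elif t == 1:
            e = e01
            c2 = c01
        else:
            e = e11
            c2 = c11
        if r2 >= c2 or r2 <= zero:
            continue
        if r2 < F32(0.01):  # overlap floor: keeps float32 finite, cap clips anyway
            r2 = F32(0.01)
        inv2 = F32(1.0) / r2
        inv6 = inv2 * inv2 * inv2
        f = F32(24.0) * e * (F32(2.0) * inv6 * inv6 - inv6) * inv2
        if force_cap > zero:
            q = f * f * r2
            if q > cap2:
                f = f * force_cap / np.sqrt(q)
        forces[i, 0] -= f * d0
        forces[i, 1] -= f * d1
        forces[i, 2] -= f * d2
        forces[j, 0] += f * d0
        forces[j, 1] += f * d1
        forces[j, 2] += f * d2
    R02 = fene_R0 * fene_R0
    for i in range(n - 1):
        j = i + 1
        d0 = pos[j, 0] - pos[i, 0]
        d1 = pos[j, 1] - pos[i, 1]
        d2 = pos[j, 2] - pos[i, 2]
        if periodic:
            d0 -= box * F32(np.rint(d0 / box))
            d1 -= box * F32(np.rint(d1 / box))
            d2 -= box * F32(np.rint(d2 / box))
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 >= R02:
            return ERR_OVEREXTENSION
        f = -fene_K / (F32(1.0) - r2 / R02)
        if zero < r2 < wca_cut2:
            if marks[i] + marks[j] == 0:
                e = e00
            elif marks[i] + marks[j] == 1:
                e = e01
            else:
                e = e11
            inv2 = F32(1.0) / r2
            inv6 = inv2 * inv2 * inv2
            fw = F32(24.0) * e * (F32(2.0) * inv6 * inv6 - inv6) * inv2
            if force_cap > zero:
                q = fw * fw * r2
                if q > cap2:
                    fw = fw * force_cap / np.sqrt(q)
            f += fw
        forces[i, 0] -= f * d0
        forces[i, 1] -= f * d1
        forces[i, 2] -= f * d2
        forces[j, 0] += f * d0
        forces[j, 1] += f * d1
        forces[j, 2] += f * d2
    return OK


@njit(cache=True, fastmath=True)
def _bead_energy32(pos, marks, i, mark_i, skip, eps, cut2, shift, wca_cut2, box, periodic):
    n = pos.shape[0]
    etot = 0.0
    for k in range(n):
        if k == i or k == skip:
            continue
        d0 = pos[k, 0] - pos[i, 0]
        d1 = pos[k, 1] - pos[i, 1]
        d2 = pos[k, 2] - pos[i, 2]
        if periodic:
            d0 -= box * F32(np.rint(d0 / box))
            d1 -= box * F32(np.rint(d1 / box))
            d2 -= box * F32(np.rint(d2 / box))
        r2 = np.float64(d0 * d0 + d1 * d1 + d2 * d2)
        mk = marks[k]
        bonded = k == i - 1 or k == i + 1
        etot += _bead_pair_energy(
            r2, bonded, eps[mark_i, mk], cut2[mark_i, mk], shift[mark_i, mk], wca_cut2
        )
    return etot


@njit(cache=True, fastmath=True)
def _exchange_move32(pos, marks, labels, rng, eps, cut2, shift, wca_cut2, r_neigh2, T_E, box, periodic, counters):
    n = marks.shape[0]
    counters[C_EXCH_PROP] += 1
    i = _randint(rng, n)
    # uniform choice among spatial neighbours by reservoir sampling
    j = -1
    cnt = 0
    for k in range(n):
        if k == i:
            continue
        d0 = pos[k, 0] - pos[i, 0]
        d1 = pos[k, 1] - pos[i, 1]
        d2 = pos[k, 2] - pos[i, 2]
        if periodic:
            d0 -= box * F32(np.rint(d0 / box))
            d1 -= box * F32(np.rint(d1 / box))
            d2 -= box * F32(np.rint(d2 / box))
        if d0 * d0 + d1 * d1 + d2 * d2 < r_neigh2:
            cnt += 1
            if _uniform(rng) * cnt < 1.0:
                j = k
    if j < 0:
        counters[C_EXCH_NOOP] += 1
        return
    if marks[i] == marks[j]:
        # identity on the mark field, but the tagged labels still hop:
        # same-mark Kawasaki swaps have dE = 0 and are always accepted
        tl = labels[i]
        labels[i] = labels[j]
        labels[j] = tl
        counters[C_EXCH_TRIVIAL] += 1
        return
    mi = marks[i]
    mj = marks[j]
    before = _bead_energy32(pos, marks, i, mi, j, eps, cut2, shift, wca_cut2, box, periodic)
    before += _bead_energy32(pos, marks, j, mj, i, eps, cut2, shift, wca_cut2, box, periodic)
    after = _bead_energy32(pos, marks, i, mj, j, eps, cut2, shift, wca_cut2, box, periodic)
    after += _bead_energy32(pos, marks, j, mi, i, eps, cut2, shift, wca_cut2, box, periodic)
    dE = after - before
    accept = dE <= 0.0
    if not accept:
        accept = _uniform(rng) < np.exp(-dE / T_E)
    if accept:
        marks[i] = mj
        marks[j] = mi
        tl = labels[i]
        labels[i] = labels[j]
        labels[j] = tl
        counters[C_EXCH_ACC] += 1
    else:
        counters[C_EXCH_REJ] += 1


@njit(cache=True)
def _reaction_move(marks, rng, p_ac, counters):
    n = marks.shape[0]
    counters[C_REACT_MOVES] += 1
    i = _randint(rng, n)
    if _uniform(rng) < p_ac:
        if marks[i] != 0:
            counters[C_REACT_TO_E] += 1
        marks[i] = 0
    else:
        if marks[i] != 1:
            counters[C_REACT_TO_H] += 1
        marks[i] = 1


@njit(cache=True, fastmath=True)
def run_kernel(
    pos,
    marks,
    labels,
    n_steps,
    step0,
    dt,
    n_substeps,
    d_bead,
    mobility,
    cap,
    force_cap,
    box,
    periodic,
    eps,
    cut2,
    shift,
    fene_K,
    fene_R0,
    wca_cut2,
    T_E,
    r_neigh2,
    p_ac,
    do_exchange,
    do_reaction,
    exchange_every,
    reaction_every,
    frame_stride,
    seed,
    skin,
    f_pos,
    f_marks,
    f_labels,
    f_steps,
    counters,
):
    """Advance ``n_steps`` of interleaved Brownian motion, mark exchange and
    reactions, writing frames every ``frame_stride`` steps (frame 0 is the
    entry state).  Mutates pos/marks/labels in place; returns an exit code.

    Each scheduling step spans ``dt`` of model time, integrated with
    ``n_substeps`` Euler-Maruyama substeps; exchange and reaction cadences
    count scheduling steps (on the absolute step number step0 + s, so split
    segments of one run schedule identically).  A substep that overstretches
    a bond is rejected and retried with a halved displacement cap.
    """
    n = pos.shape[0]
    rng_m = np.zeros(2, dtype=np.uint64)
    rng_e = np.zeros(2, dtype=np.uint64)
    rng_r = np.zeros(2, dtype=np.uint64)
    _pcg_init(rng_m, seed, 1)
    _pcg_init(rng_e, seed, 2)
    _pcg_init(rng_r, seed, 3)

    p32 = pos.astype(F32)
    box32 = F32(box)
    e00 = F32(eps[0, 0])
    e01 = F32(eps[0, 1])
    e11 = F32(eps[1, 1])
    c00 = F32(cut2[0, 0])
    c01 = F32(cut2[0, 1])
    c11 = F32(cut2[1, 1])
    eps32 = eps.astype(F32)
    cut2_32 = cut2.astype(F32)
    shift32 = shift.astype(F32)
    K32 = F32(fene_K)
    R032 = F32(fene_R0)
    wca32 = F32(wca_cut2)
    fcap32 = F32(force_cap)
    rn2_32 = F32(r_neigh2)

    noise = np.empty(3 * n, dtype=F32)
    forces = np.empty((n, 3), dtype=F32)
    disp = np.zeros((n, 3), dtype=F32)
    pos_old = np.empty((n, 3), dtype=F32)

    rlist = np.sqrt(np.max(cut2)) + skin
    rlist2_32 = F32(rlist * rlist)
    cap_pairs = max(96 * n, 4096)
    pi = np.empty(cap_pairs, dtype=np.int32)
    pj = np.empty(cap_pairs, dtype=np.int32)
    n_pairs = build_pairs_cells(p32, rlist2_32, box32, periodic, pi, pj)
    while n_pairs > pi.shape[0]:
        cap_pairs = 2 * n_pairs
        pi = np.empty(cap_pairs, dtype=np.int32)
        pj = np.empty(cap_pairs, dtype=np.int32)
        n_pairs = build_pairs_cells(p32, rlist2_32, box32, periodic, pi, pj)
    counters[C_REBUILDS] += 1

    # frame 0: entry state
    frame = 0
    for i in range(n):
        f_pos[frame, i, 0] = p32[i, 0]
        f_pos[frame, i, 1] = p32[i, 1]
        f_pos[frame, i, 2] = p32[i, 2]
        f_marks[frame, i] = marks[i]
        f_labels[frame, i] = labels[i]
    f_steps[frame] = step0
    frame += 1

    dt_sub = dt / n_substeps
    amp = F32(np.sqrt(2.0 * d_bead * dt_sub))
    mob_dt = F32(mobility * dt_sub)
    cap32 = F32(cap)
    half_skin2 = F32((0.5 * skin) * (0.5 * skin))
    zero = F32(0.0)
    R02 = R032 * R032
    R02_guard = F32(0.995) * R02

    for s in range(n_steps):
      for _sub in range(n_substeps):
        code = _forces32(
            p32, marks, n_pairs, pi, pj, e00, e01, e11, c00, c01, c11,
            K32, R032, wca32, box32, periodic, forces, fcap32,
        )
        if code != OK:
            return code
        _fill_normals32(rng_m, noise)
        for i in range(n):
            pos_old[i, 0] = p32[i, 0]
            pos_old[i, 1] = p32[i, 1]
            pos_old[i, 2] = p32[i, 2]
        # a substep that overstretches a bond is rejected and retried with
        # a halved displacement cap (same forces, same noise draw)
        capl = cap32
        ok_step = False
        for _retry in range(10):
            for i in range(n):
                dx = mob_dt * forces[i, 0] + amp * noise[3 * i]
                dy = mob_dt * forces[i, 1] + amp * noise[3 * i + 1]
                dz = mob_dt * forces[i, 2] + amp * noise[3 * i + 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > capl * capl:
                    fac = capl / np.sqrt(d2)
                    dx *= fac
                    dy *= fac
                    dz *= fac
                    counters[C_CAP_HITS] += 1
                x = pos_old[i, 0] + dx
                y = pos_old[i, 1] + dy
                z = pos_old[i, 2] + dz
                if periodic:
                    x -= box32 * F32(np.floor(x / box32))
                    y -= box32 * F32(np.floor(y / box32))
                    z -= box32 * F32(np.floor(z / box32))
                else:
                    if x < zero:
                        x = -x
                    elif x > box32:
                        x = box32 + box32 - x
                    if y < zero:
                        y = -y
                    elif y > box32:
                        y = box32 + box32 - y
                    if z < zero:
                        z = -z
                    elif z > box32:
                        z = box32 + box32 - z
                p32[i, 0] = x
                p32[i, 1] = y
                p32[i, 2] = z
            ok_step = True
            for i in range(n - 1):
                d0 = p32[i + 1, 0] - p32[i, 0]
                d1 = p32[i + 1, 1] - p32[i, 1]
                d2b = p32[i + 1, 2] - p32[i, 2]
                if periodic:
                    d0 -= box32 * F32(np.rint(d0 / box32))
                    d1 -= box32 * F32(np.rint(d1 / box32))
                    d2b -= box32 * F32(np.rint(d2b / box32))
                if d0 * d0 + d1 * d1 + d2b * d2b >= R02_guard:
                    ok_step = False
                    break
            if ok_step:
                break
            capl *= F32(0.5)
        if not ok_step:
            return ERR_OVEREXTENSION
        max_d2 = zero
        for i in range(n):
            disp[i, 0] += p32[i, 0] - pos_old[i, 0]
            disp[i, 1] += p32[i, 1] - pos_old[i, 1]
            disp[i, 2] += p32[i, 2] - pos_old[i, 2]
            dd = disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2
            if dd > max_d2:
                max_d2 = dd
        if not np.isfinite(max_d2):
            return ERR_NONFINITE
        if max_d2 > half_skin2:
            n_pairs = build_pairs_cells(p32, rlist2_32, box32, periodic, pi, pj)
            while n_pairs > pi.shape[0]:
                cap_pairs = 2 * n_pairs
                pi = np.empty(cap_pairs, dtype=np.int32)
                pj = np.empty(cap_pairs, dtype=np.int32)
                n_pairs = build_pairs_cells(p32, rlist2_32, box32, periodic, pi, pj)
            counters[C_REBUILDS] += 1
            for i in range(n):
                disp[i, 0] = zero
                disp[i, 1] = zero
                disp[i, 2] = zero

      abs_step = step0 + s + 1
      if do_exchange and abs_step % exchange_every == 0:
          _exchange_move32(
              p32, marks, labels, rng_e, eps32, cut2_32, shift32, wca_cut2,
              rn2_32, T_E, box32, periodic, counters,
          )
      if do_reaction and abs_step % reaction_every == 0:
          _reaction_move(marks, rng_r, p_ac, counters)

      if (s + 1) % frame_stride == 0 or s == n_steps - 1:
          for i in range(n):
              f_pos[frame, i, 0] = p32[i, 0]
              f_pos[frame, i, 1] = p32[i, 1]
              f_pos[frame, i, 2] = p32[i, 2]
              f_marks[frame, i] = marks[i]
              f_labels[frame, i] = labels[i]
          f_steps[frame] = abs_step
          frame += 1

    for i in range(n):
        pos[i, 0] = p32[i, 0]
        pos[i, 1] = p32[i, 1]
        pos[i, 2] = p32[i, 2]
    return OK
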