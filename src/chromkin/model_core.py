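"""Pair and bond potentials, total energy, and neighbor search.

This module is the plain-numpy reference for the force field; the production
integrator in :mod:`chromkin._kernels` reimplements the same expressions in
numba and is tested against these functions.

Nonbonded pairs interact through a truncated-and-shifted 12-6 Lennard-Jones
potential whose well depth and cutoff depend on the (mark_i, mark_j) pair:
like pairs (E-E, H-H) are attractive with cutoff ``cut_attractive``, the
unlike E-H pair is cut at the potential minimum 2^(1/6) sigma, i.e. a purely
repulsive WCA core.  Bonded (consecutive) beads feel a FENE spring plus the
WCA core of the pair and are excluded from the nonbonded sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams
from .state import SimulationState


def _lj(eps: float, r: np.ndarray | float) -> np.ndarray | float:
    sr6 = 1.0 / np.asarray(r, dtype=np.float64) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def pair_potential(mark_i: int, mark_j: int, r: float, params: ModelParams) -> float:
    """Truncated-and-shifted LJ energy (kT) between two nonbonded beads.

    Symmetric in the two marks.  Zero at and beyond the pair's cutoff; the
    shift makes the potential continuous there.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    eps = params.eps_matrix()[mark_i, mark_j]
    cut = params.cut_matrix()[mark_i, mark_j]
    if r >= cut:
        return 0.0
    return float(_lj(eps, r) - _lj(eps, cut))


def bond_potential(r: float, params: ModelParams, mark_i: int = 0, mark_j: int = 0) -> float:
    """FENE + WCA energy (kT) of a bonded pair at separation ``r``.

    The FENE term -0.5 K R0^2 ln(1 - (r/R0)^2) diverges at the maximum
    extension R0; the WCA core (depth set by the pair's epsilon, shifted so it
    vanishes at 2^(1/6) sigma) prevents overlap.
    """
    if r < 0:
        raise ValueError("bond length must be nonnegative")
    if r >= params.fene_R0:
        raise OverextensionError(f"bond length {r} >= fene_R0 {params.fene_R0}")
    fene = -0.5 * params.fene_K * params.fene_R0**2 * np.log(1.0 - (r / params.fene_R0) ** 2)
    eps = params.eps_matrix()[mark_i, mark_j]
    wca = 0.0
    if 0 < r < params.cut_repulsive:
        wca = _lj(eps, r) + eps
    return float(fene + wca)


class OverextensionError(RuntimeError):
    """A bond exceeded the FENE maximum extension."""


class StaleNeighborListError(RuntimeError):
    """The neighbor list no longer covers the current positions."""


def chain_bonds(n: int) -> np.ndarray:
    """Bond list of a linear chain: (i, i+1) pairs."""
    idx = np.arange(n - 1)
    return np.column_stack([idx, idx + 1]).astype(np.int64)


@dataclass
class NeighborList:
    """Verlet pair list within ``cutoff + skin``, with rebuild bookkeeping."""

    pairs: np.ndarray  # (M, 2) int64, i < j
    cutoff: float
    skin: float
    reference_positions: np.ndarray

    def is_stale(self, positions: np.ndarray) -> bool:
        disp = np.linalg.norm(positions - self.reference_positions, axis=1)
        return bool(disp.max(initial=0.0) > 0.5 * self.skin)


def build_neighbor_list(
    positions: np.ndarray,
    cutoff: float,
    skin: float = 0.5,
    boundary_mode: str = "reflective",
    box_side: float | None = None,
) -> NeighborList:
    """All pairs within ``cutoff + skin`` by a direct O(N^2) scan.

    With ``boundary_mode='periodic'`` the minimum-image convention is used
    (``box_side`` required); reflective boxes use plain Euclidean distance.
    """
    positions = np.asarray(positions, dtype=np.float64)
    if not np.isfinite(positions).all():
        raise ValueError("non-finite coordinates")
    if cutoff <= 0 or skin < 0:
        raise ValueError("cutoff must be positive and skin nonnegative")
    d = positions[:, None, :] - positions[None, :, :]
    if boundary_mode == "periodic":
        if box_side is None:
            raise ValueError("periodic boundaries need box_side")
        d -= box_side * np.round(d / box_side)
    r = np.sqrt((d**2).sum(-1))
    iu = np.triu_indices(len(positions), k=1)
    keep = r[iu] < cutoff + skin
    pairs = np.column_stack([iu[0][keep], iu[1][keep]]).astype(np.int64)
    return NeighborList(pairs=pairs, cutoff=cutoff, skin=skin, reference_positions=positions.copy())


def _pair_displacements(positions, i, j, params: ModelParams):
    d = positions[j] - positions[i]
    if params.boundary_mode == "periodic":
        box = params.box_for(len(positions))
        d -= box * np.round(d / box)
    return d


def total_energy(
    state: SimulationState,
    params: ModelParams,
    nl: NeighborList | None = None,
    bonds: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(bonded, nonbonded, total) energy in kT.

    ``bonds`` defaults to the linear chain.  When ``nl`` is given it must be
    fresh for the current positions; pass ``nl=None`` for an exact all-pairs
    evaluation.
    """
    pos = state.positions
    marks = np.asarray(state.marks, dtype=np.intp)
    n = len(pos)
    if bonds is None:
        bonds = chain_bonds(n)
    if nl is None:
        nl = build_neighbor_list(
            pos,
            params.cut_attractive,
            skin=0.0,
            boundary_mode=params.boundary_mode,
            box_side=params.box_for(n),
        )
    elif nl.is_stale(pos):
        raise StaleNeighborListError("neighbor list requires rebuild")

    bonded = 0.0
    bond_set = set()
    for i, j in bonds:
        d = _pair_displacements(pos, int(i), int(j), params)
        r = float(np.linalg.norm(d))
        if r >= params.fene_R0:
            raise OverextensionError(f"bond ({i}, {j}) overextended: r = {r:.4f}")
        bonded += bond_potential(r, params, marks[i], marks[j])
        bond_set.add((min(i, j), max(i, j)))

    nonbonded = 0.0
    for i, j in nl.pairs:
        if (min(i, j), max(i, j)) in bond_set:
            continue
        d = _pair_displacements(pos, int(i), int(j), params)
        r = float(np.linalg.norm(d))
        if r > 0:
            nonbonded += pair_potential(marks[i], marks[j], r, params)
    return bonded, nonbonded, bonded + nonbonded


def compute_forces(
    positions: np.ndarray,
    marks: np.ndarray,
    params: ModelParams,
    nl: NeighborList,
    bonds: np.ndarray | None = None,
) -> np.ndarray:
    """Reference force evaluation, -grad of the energy above."""
    pos = np.asarray(positions, dtype=np.float64)
    marks = np.asarray(marks, dtype=np.intp)
    n = len(pos)
    if bonds is None:
        bonds = chain_bonds(n)
    eps_m = params.eps_matrix()
    cut_m = params.cut_matrix()
    forces = np.zeros_like(pos)
    bond_set = {(min(i, j), max(i, j)) for i, j in bonds}

    for i, j in nl.pairs:
        key = (min(i, j), max(i, j))
        if key in bond_set:
            continue
        d = _pair_displacements(pos, int(i), int(j), params)
        r2 = float(d @ d)
        eps = eps_m[marks[i], marks[j]]
        cut = cut_m[marks[i], marks[j]]
        if r2 >= cut * cut or r2 == 0.0:
            continue
        inv6 = 1.0 / r2**3
        # dV/dr * (1/r) = 24 eps (inv6 - 2 inv12) / r^2
        fmag_over_r = 24.0 * eps * (2.0 * inv6 * inv6 - inv6) / r2
        forces[i] -= fmag_over_r * d
        forces[j] += fmag_over_r * d

    K, R0 = params.fene_K, params.fene_R0
    for i, j in bonds:
        d = _pair_displacements(pos, int(i), int(j), params)
        r2 = float(d @ d)
        if r2 >= R0 * R0:
            raise OverextensionError(f"bond ({i}, {j}) overextended")
        # FENE: dV/dr = K r / (1 - (r/R0)^2)
        fmag_over_r = -K / (1.0 - r2 / (R0 * R0))
        eps = eps_m[marks[i], marks[j]]
        if 0.0 < r2 < params.cut_repulsive**2:
            inv6 = 1.0 / r2**3
            fmag_over_r += 24.0 * eps * (2.0 * inv6 * inv6 - inv6) / r2
        forces[i] -= fmag_over_r * d
        forces[j] += fmag_over_r * d
    return forces
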