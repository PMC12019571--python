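"""Monte-Carlo mark kinetics: Kawasaki-style exchange and active reactions.

Two processes act on the epigenetic marks while positions are fixed:

* ``exchange_move`` swaps the marks of a random bead and a random *spatial*
  neighbour (within ``r_neigh``, 3D proximity, not chain adjacency) with the
  Metropolis probability min(1, exp(-dE/T_E)).  It conserves the H/E counts
  exactly and satisfies detailed balance at temperature ``T_E`` -- marks
  diffuse without being created or destroyed.
* ``reaction_move`` resets a uniformly chosen bead to E with probability
  p_ac = gamma_ac/(gamma_ac+gamma_me) and to H otherwise, regardless of its
  current mark.  This is the active, detailed-balance-breaking process that
  models histone acetyl/methyl writer-eraser activity; its reaction-only
  stationary H fraction is gamma_me/(gamma_me+gamma_ac).

These are the reference single-move implementations; the production loop in
:mod:`chromkin._kernels` inlines the same logic.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .params import KineticsParams, ModelParams
from .state import SimulationState


def swap_delta_energy(
    state: SimulationState, i: int, j: int, params: ModelParams
) -> float:
    """Energy change (kT) of swapping the marks of beads i and j.

    Only the pair terms touching i or j can change, and the (i, j) pair
    itself is invariant because the pair epsilon is symmetric in the marks.
    """
    box = params.box_for(state.n_beads)
    return float(
        _kernels.exchange_delta_e(
            state.positions,
            state.marks,
            int(i),
            int(j),
            params.eps_matrix(),
            params.cut_matrix() ** 2,
            _shift_matrix(params),
            params.cut_repulsive**2,
            box,
            params.boundary_mode == "periodic",
        )
    )


def _shift_matrix(params: ModelParams) -> np.ndarray:
    eps = params.eps_matrix()
    cut = params.cut_matrix()
    sr6 = 1.0 / cut**6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def exchange_move(
    state: SimulationState,
    params: ModelParams,
    kin: KineticsParams,
    rng: np.random.Generator,
) -> tuple[SimulationState, bool]:
    """One in-place exchange proposal.  Returns (state, accepted).

    Same-mark proposals are no-ops counted as trivially accepted (dE = 0);
    a bead with no neighbour within ``r_neigh`` is a rejected no-op.
    """
    n = state.n_beads
    i = int(rng.integers(n))
    d = state.positions - state.positions[i]
    if params.boundary_mode == "periodic":
        box = params.box_for(n)
        d -= box * np.round(d / box)
    r2 = (d**2).sum(axis=1)
    cand = np.flatnonzero(r2 < kin.r_neigh**2)
    cand = cand[cand != i]
    if cand.size == 0:
        return state, False
    j = int(cand[rng.integers(cand.size)])
    if state.marks[i] == state.marks[j]:
        # dE = 0: always accepted; the mark field is unchanged but tagged
        # labels still hop, which is what the diffusivity estimate tracks
        if state.labels is not None:
            state.labels[i], state.labels[j] = state.labels[j], state.labels[i]
        return state, True
    dE = swap_delta_energy(state, i, j, params)
    if dE <= 0.0 or rng.random() < np.exp(-dE / kin.T_E):
        state.marks[i], state.marks[j] = state.marks[j], state.marks[i]
        if state.labels is not None:
            state.labels[i], state.labels[j] = state.labels[j], state.labels[i]
        return state, True
    return state, False


def reaction_move(
    state: SimulationState, kin: KineticsParams, rng: np.random.Generator
) -> SimulationState:
    """One in-place active reset of a uniformly chosen bead."""
    p_ac = kin.p_ac  # raises if both rates are zero
    i = int(rng.integers(state.n_beads))
    state.marks[i] = 0 if rng.random() < p_ac else 1
    return state


def reaction_only_series(
    marks0: np.ndarray, kin: KineticsParams, n_moves: int, rng: np.random.Generator
) -> np.ndarray:
    """H-fraction time series of the pure reaction chain (no motion/exchange).

    Vectorized: move t hits bead ``idx[t]`` and resets it to H with
    probability p_me.  Used for stationary-composition measurements.
    """
    marks = np.asarray(marks0, dtype=np.uint8).copy()
    n = len(marks)
    idx = rng.integers(n, size=n_moves)
    to_h = rng.random(n_moves) >= kin.p_ac
    h_frac = np.empty(n_moves)
    h = int((marks == 1).sum())
    for t in range(n_moves):
        i = idx[t]
        new = 1 if to_h[t] else 0
        h += int(new) - int(marks[i])
        marks[i] = new
        h_frac[t] = h / n
    return h_frac
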