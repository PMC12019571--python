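"""Overdamped Brownian integration, relaxation, and the protocol scheduler.

The integrator is first-order position-Langevin: each step every coordinate
moves by mobility * F * dt plus Gaussian noise of variance 2 D dt.  A single
overdamped integrator serves both the relaxation stage and the production
dynamics -- at chromatin scales inertia is irrelevant and the Brownian time
tau_Br anchors the physics.  The scheduler interleaves one exchange proposal
every ``exchange_every`` steps and one reaction move every
``reaction_every`` steps, matching the model's cadence convention (defaults:
exchange each step, reaction every 10^3 steps).
"""

from __future__ import annotations

import logging

import numpy as np

from . import _kernels, model_core
from .params import DynamicsParams, KineticsParams, ModelParams, Phase, Protocol, params_to_json
from .state import SimulationState, Trajectory

log = logging.getLogger(__name__)


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return z ^ (z >> 31)


def derive_seed(seed: int, *path: int) -> int:
    """Deterministically derive a sub-seed for a run segment / replicate."""
    x = seed & 0xFFFFFFFFFFFFFFFF
    for p in path:
        x = _splitmix64(x ^ _splitmix64(p))
    return x & 0x7FFFFFFFFFFFFFFF  # fits in int64 for the numba kernel


class KernelError(RuntimeError):
    pass


def _kernel_args(params: ModelParams, n_beads: int):
    eps = params.eps_matrix()
    cut = params.cut_matrix()
    sr6 = 1.0 / cut**6
    shift = 4.0 * eps * (sr6 * sr6 - sr6)
    return (
        params.box_for(n_beads),
        params.boundary_mode == "periodic",
        eps,
        cut**2,
        shift,
        params.fene_K,
        params.fene_R0,
        params.cut_repulsive**2,
    )


def brownian_step(
    state: SimulationState,
    params: ModelParams,
    dyn: DynamicsParams,
    rng: np.random.Generator,
    noise: bool = True,
    external_force: np.ndarray | None = None,
    bonds: np.ndarray | None = None,
) -> SimulationState:
    """One reference Euler-Maruyama step (numpy path, used by tests).

    ``noise=False`` switches the stochastic term off to expose the pure
    drift; ``external_force`` adds a constant test force per bead.
    """
    n = state.n_beads
    nl = model_core.build_neighbor_list(
        state.positions,
        params.cut_attractive,
        skin=0.0,
        boundary_mode=params.boundary_mode,
        box_side=params.box_for(n),
    )
    forces = model_core.compute_forces(state.positions, state.marks, params, nl, bonds=bonds)
    if external_force is not None:
        forces = forces + external_force
    if not np.isfinite(forces).all():
        bad = int(np.flatnonzero(~np.isfinite(forces).all(axis=1))[0])
        raise KernelError(f"non-finite force on bead {bad}")
    dt = dyn.dt_reduced
    disp = dyn.mobility * forces * dt
    if noise:
        disp = disp + np.sqrt(2.0 * dyn.d_bead * dt) * rng.standard_normal((n, 3))
    mag = np.linalg.norm(disp, axis=1)
    over = mag > dyn.displacement_cap
    if over.any():
        disp[over] *= (dyn.displacement_cap / mag[over])[:, None]
    pos = state.positions + disp
    box = params.box_for(n)
    if params.boundary_mode == "periodic":
        pos -= box * np.floor(pos / box)
    else:
        pos = np.where(pos < 0, -pos, pos)
        pos = np.where(pos > box, 2 * box - pos, pos)
    return SimulationState(
        positions=pos,
        marks=state.marks.copy(),
        step=state.step + 1,
        sim_time=state.sim_time + dt,
        rng_seed=state.rng_seed,
        labels=None if state.labels is None else state.labels.copy(),
    )


def _run_segment(
    state: SimulationState,
    params: ModelParams,
    dyn: DynamicsParams,
    phase: Phase,
    seed: int,
    kin: KineticsParams | None = None,
    skin: float = 0.8,
) -> tuple[SimulationState, Trajectory, np.ndarray]:
    """Drive the numba kernel for one phase; returns (state, traj, counters)."""
    n = state.n_beads
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    marks = np.ascontiguousarray(state.marks, dtype=np.uint8)
    labels = (
        np.arange(n, dtype=np.int32)
        if state.labels is None
        else np.ascontiguousarray(state.labels, dtype=np.int32)
    )
    n_frames = phase.n_steps // phase.frame_stride + 1
    if phase.n_steps % phase.frame_stride:
        n_frames += 1  # kernel appends a final frame off the stride grid
    f_pos = np.empty((n_frames, n, 3), dtype=np.float32)
    f_marks = np.empty((n_frames, n), dtype=np.uint8)
    f_labels = np.empty((n_frames, n), dtype=np.int32)
    f_steps = np.empty(n_frames, dtype=np.int64)
    counters = np.zeros(_kernels.N_COUNTERS, dtype=np.int64)

    do_reaction = phase.gamma_ac + phase.gamma_me > 0
    p_ac = phase.gamma_ac / (phase.gamma_ac + phase.gamma_me) if do_reaction else 0.0
    if kin is None:
        kin = KineticsParams(gamma_ac=max(phase.gamma_ac, 1e-12), gamma_me=phase.gamma_me)
    box, periodic, eps, cut2, shift, K, R0, wca2 = _kernel_args(params, n)

    code = _kernels.run_kernel(
        pos,
        marks,
        labels,
        phase.n_steps,
        state.step,
        dyn.dt_reduced,
        dyn.n_substeps,
        dyn.d_bead,
        dyn.mobility,
        dyn.displacement_cap,
        dyn.force_cap,
        box,
        periodic,
        eps,
        cut2,
        shift,
        K,
        R0,
        wca2,
        kin.T_E,
        kin.r_neigh**2,
        p_ac,
        phase.exchange_every > 0,
        do_reaction,
        max(phase.exchange_every, 1),
        phase.reaction_every,
        phase.frame_stride,
        seed & 0xFFFFFFFFFFFFFFFF,
        skin,
        f_pos,
        f_marks,
        f_labels,
        f_steps,
        counters,
    )
    if code == _kernels.ERR_OVEREXTENSION:
        raise model_core.OverextensionError("bond overextended during kernel run")
    if code == _kernels.ERR_NONFINITE:
        raise KernelError("non-finite displacement; simulation diverged")

    new_state = SimulationState(
        positions=pos,
        marks=marks,
        step=state.step + phase.n_steps,
        sim_time=state.sim_time + phase.n_steps * dyn.dt_reduced,
        rng_seed=state.rng_seed,
        labels=labels,
    )
    traj = Trajectory(
        positions=f_pos,
        marks=f_marks,
        steps=f_steps,
        times=f_steps * dyn.dt_reduced,
        labels=f_labels,
    )
    return new_state, traj, counters


def relax(
    state: SimulationState,
    params: ModelParams,
    dyn: DynamicsParams,
    max_steps: int = 200_000,
    plateau_tol: float = 1e-3,
    block_steps: int = 10_000,
    seed: int = 0,
) -> tuple[SimulationState, bool]:
    """Motion-only dynamics until the block-averaged energy plateaus.

    Within each block of ``block_steps`` the total energy is sampled several
    times; relaxation stops once the mean energy no longer drops from one
    block to the next beyond the larger of its own sampling noise (2 SE) and
    ``plateau_tol`` relative -- a fluctuating equilibrium energy never
    settles pointwise, so the criterion must be statistical.
    Returns (state, plateau_reached).
    """
    box, periodic, eps, cut2, shift, K, R0, wca2 = _kernel_args(params, state.n_beads)

    def energy(s):
        e_b, e_nb = _kernels.total_energy(
            s.positions, s.marks, eps, cut2, shift, K, R0, wca2, box, periodic
        )
        return e_b + e_nb

    if not np.isfinite(energy(state)):
        raise KernelError("divergent energy at relaxation start")
    n_samples = 8
    sub = max(block_steps // n_samples, 1)
    done = 0
    block = 0
    prev_mean = None
    while done < max_steps:
        es = []
        for k in range(n_samples):
            n_now = min(sub, max_steps - done)
            if n_now <= 0:
                break
            phase = Phase(
                n_steps=n_now, gamma_ac=0.0, gamma_me=0.0,
                exchange_every=0, frame_stride=max(n_now, 1),
            )
            state, _, _ = _run_segment(
                state, params, dyn, phase, derive_seed(seed, 101, block, k)
            )
            done += n_now
            e = energy(state)
            if not np.isfinite(e):
                raise KernelError("divergent energy during relaxation")
            es.append(e)
        m = float(np.mean(es))
        noise = 2.0 * float(np.std(es)) / np.sqrt(len(es))
        if prev_mean is not None:
            drop = prev_mean - m
            if drop < max(noise, plateau_tol * abs(m)):
                return state, True
        prev_mean = m
        block += 1
    log.info("relaxation hit max_steps=%d without energy plateau", max_steps)
    return state, False


def run_protocol(
    state: SimulationState,
    params: ModelParams,
    dyn: DynamicsParams,
    protocol: Protocol,
    seed: int,
    kin: KineticsParams | None = None,
) -> Trajectory:
    """Execute all phases back to back and return the stitched trajectory.

    With every phase's reaction rates at zero the multiset of marks is
    conserved exactly (Kawasaki exchange only permutes labels).
    """
    if state.labels is None:
        state = state.copy()
        state.labels = np.arange(state.n_beads, dtype=np.int32)
    traj: Trajectory | None = None
    all_counters = []
    for k, phase in enumerate(protocol.phases):
        state, seg, counters = _run_segment(state, params, dyn, phase, derive_seed(seed, 7, k), kin=kin)
        all_counters.append({
            "phase": k,
            "exchange_proposals": int(counters[_kernels.C_EXCH_PROP]),
            "exchange_trivial": int(counters[_kernels.C_EXCH_TRIVIAL]),
            "exchange_accepted": int(counters[_kernels.C_EXCH_ACC]),
            "exchange_rejected": int(counters[_kernels.C_EXCH_REJ]),
            "exchange_no_neighbor": int(counters[_kernels.C_EXCH_NOOP]),
            "reaction_moves": int(counters[_kernels.C_REACT_MOVES]),
            "reactions_to_E": int(counters[_kernels.C_REACT_TO_E]),
            "reactions_to_H": int(counters[_kernels.C_REACT_TO_H]),
            "displacement_cap_hits": int(counters[_kernels.C_CAP_HITS]),
            "neighbor_rebuilds": int(counters[_kernels.C_REBUILDS]),
        })
        traj = seg if traj is None else traj.concat(seg)
    assert traj is not None
    traj.metadata = {
        "seed": int(seed),
        "model": params_to_json(params),
        "dynamics": params_to_json(dyn),
        "protocol": params_to_json(protocol),
        "counters": all_counters,
        "tau_br_s": dyn.tau_br,
        "gamma_rates": [(p.gamma_ac, p.gamma_me) for p in protocol.phases],
    }
    return traj
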