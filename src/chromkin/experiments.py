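"""Config-driven in-silico experiments.

Three reproducible protocols operate on synthetic (or file-derived) tracks:

* a scaling sweep over exchange cadence and/or reaction rates that measures
  steady-state domain radii and fits the reaction-diffusion scaling law;
* a paired perturbation experiment (balanced control arm versus shifted
  methylation:acetylation ratio) that reports the percent change in domain
  radius, per-replicate mark conservation, ensemble flipping scores and
  their boundary enrichment;
* a two-phase memory experiment (acetylation stimulus for t', then enhanced
  methylation for t') with conserved/memory/recovered bead classes.

Horizons are expressed in hours of real time and converted to steps with
dt = 0.01 tau_Br = 3 ms.  Because the reference chromosome of the full-scale
runs (chr19 at 10 kb bins) is ~5860 beads while desk-scale polymers are a
few hundred, horizons are scaled by n_beads / 5860 so per-bead exchange and
reaction doses are preserved; the ``scale`` config key overrides this.
"""

from __future__ import annotations

import numpy as np

from . import analysis
from .dynamics import derive_seed, relax, run_protocol
from .genome_io import CompartmentTrack, init_conformation, make_prototype_track
from .params import DynamicsParams, KineticsParams, ModelParams, Phase, Protocol
from .state import H

#: Bead count of the full-scale reference chromosome (chr19 at 10 kb bins).
REFERENCE_N_BEADS = 5860
#: Steps per hour of real time at dt = 3 ms.
STEPS_PER_HOUR = 1_200_000


def horizon_steps(hours: float, n_beads: int, scale: float | None = None) -> int:
    """Scaled step count for ``hours`` of real time on an n-bead polymer."""
    s = scale if scale is not None else n_beads / REFERENCE_N_BEADS
    return max(1, int(round(hours * STEPS_PER_HOUR * s)))


def _relaxed_start(track, params, dyn, seed, relax_steps):
    state = init_conformation(track, params, np.random.default_rng(seed))
    state, _ = relax(
        state, params, dyn, max_steps=relax_steps,
        block_steps=max(relax_steps // 5, 1), seed=seed,
    )
    return state


def _production_phase(n_steps, me_over_ac, frame_stride, exchange_every=1, reaction_every=1000):
    return Phase(
        n_steps=n_steps, gamma_ac=1.0, gamma_me=me_over_ac,
        exchange_every=exchange_every, reaction_every=reaction_every,
        frame_stride=frame_stride,
    )


def run_scaling_sweep(config: dict) -> dict:
    """Steady-state domain radius across exchange-cadence or rate sweeps.

    Cadence sweep points also run a reaction-free companion trajectory to
    measure the effective mark diffusivity entering the scaling predictor.
    Returns the per-point records and the OLS fit of R_d against
    sqrt((D_eff/G_ac) G_me/(G_me+G_ac)).

    The sweep's default reaction cadence is much faster than the production
    default (one move per 25 steps instead of per 1000): the scaling law
    describes the reaction-limited regime, and on desk-scale polymers a slow
    reaction rate lets the heterochromatin condense into a single
    system-spanning globule whose radius saturates regardless of the mark
    diffusivity.
    """
    seed = int(config.get("seed", 0))
    n_beads = int(config.get("n_beads", 300))
    het = float(config.get("het_fraction", 0.6))
    me_over_ac = float(config.get("me_over_ac", 1.5))
    cadences = list(config.get("exchange_every_values", [1, 2, 4, 8]))
    rate_ratios = list(config.get("rate_ratio_values", []))
    n_rep = int(config.get("n_replicates", 2))
    hours = float(config.get("hours", 2.0))
    r_c = float(config.get("r_c", 1.8))
    min_size = int(config.get("min_size", 10))
    reaction_every = int(config.get("reaction_every", 15))
    # dilute default box: at desk scale a 0.1 sigma^-3 box confines the whole
    # chain into one mixed globule where H clusters percolate; a few-fold
    # dilution lets several distinct domains form along the chain, which is
    # the regime the scaling law describes
    params = config.get("model") or ModelParams(density=0.04)
    dyn = config.get("dynamics", DynamicsParams())
    relax_steps = int(config.get("relax_steps", 30_000))
    steps = horizon_steps(hours, n_beads, config.get("scale"))
    stride = max(steps // 40, 1)

    # the prototype polymer is *randomly* labeled: near-iid marks, i.e.
    # geometric runs with E-block mean 1/het (domains must then form by mark
    # diffusion, which is what the sweep modulates)
    block = float(config.get("block_mean_len", 1.0 / max(het, 1e-6)))
    track = make_prototype_track(n_beads, het, block, seed=derive_seed(seed, 11))
    records, point_rows = [], []
    for k, ce in enumerate(cadences):
        rds, deffs = [], []
        for r in range(n_rep):
            s = derive_seed(seed, 20 + k, r)
            state = _relaxed_start(track, params, dyn, s, relax_steps)
            # short, finely sampled reaction-free companion run for D_eff
            proto_free = Protocol([Phase(
                n_steps=min(4000, steps), gamma_ac=0.0, gamma_me=0.0,
                exchange_every=ce, frame_stride=25,
            )])
            traj_free = run_protocol(state.copy(), params, dyn, proto_free, derive_seed(s, 1))
            deffs.append(analysis.estimate_mark_diffusivity(traj_free)["d_eff_sigma2_per_taubr"])
            proto = Protocol([
                _production_phase(steps, me_over_ac, stride, exchange_every=ce,
                                  reaction_every=reaction_every)
            ])
            traj = run_protocol(state, params, dyn, proto, derive_seed(s, 2))
            stats = analysis.domain_radius_series(traj, r_c, min_size)
            rds.append(stats.steady_state_mean())
        rec = analysis.ScalingRecord(
            d_eff=float(np.mean(deffs)), gamma_ac=1.0, gamma_me=me_over_ac,
            mean_rd=float(np.mean(rds)),
        )
        records.append(rec)
        point_rows.append({
            "exchange_every": ce, "d_eff": rec.d_eff, "mean_rd": rec.mean_rd,
            "rd_sd": float(np.std(rds)), "predictor": rec.predictor,
        })

    ratio_rows = []
    for k, ratio in enumerate(rate_ratios):
        rds = []
        for r in range(n_rep):
            s = derive_seed(seed, 60 + k, r)
            state = _relaxed_start(track, params, dyn, s, relax_steps)
            proto = Protocol([_production_phase(steps, ratio, stride,
                                                reaction_every=reaction_every)])
            traj = run_protocol(state, params, dyn, proto, derive_seed(s, 2))
            rds.append(analysis.domain_radius_series(traj, r_c, min_size).steady_state_mean())
        ratio_rows.append({"me_over_ac": ratio, "mean_rd": float(np.mean(rds)),
                           "rd_sd": float(np.std(rds))})

    out = {
        "experiment": "scaling_sweep",
        "seed": seed,
        "n_beads": n_beads,
        "steps": steps,
        "cadence_points": point_rows,
        "rate_points": ratio_rows,
    }
    if len(records) >= 3:
        out["fit"] = analysis.fit_domain_scaling(records)
    return out


def run_perturbation_experiment(config: dict) -> dict:
    """Paired control/perturbed arms from shared relaxed starts.

    The control arm keeps the methylation:acetylation ratio at the track's
    initial H:E ratio (composition-neutral); the perturbed arm shifts it
    (default 0.2, the hyperacetylation condition).  Reports the percent
    change in mean domain radius between arms, per-replicate conservation
    fractions, ensemble flipping scores with the averaging curve, and the
    boundary enrichment of flipped beads.
    """
    seed = int(config.get("seed", 0))
    n_beads = int(config.get("n_beads", 500))
    h_to_e = float(config.get("h_to_e_ratio", 0.45))
    het = h_to_e / (1.0 + h_to_e)
    block_len = float(config.get("block_mean_len", 25.0))
    n_tracks = int(config.get("n_tracks", 1))
    n_rep = int(config.get("n_replicates", 3))
    perturbed_ratio = float(config.get("perturbed_ratio", 0.2))
    hours = float(config.get("hours", 2.0))
    r_c = float(config.get("r_c", 1.8))
    min_size = int(config.get("min_size", 10))
    params = config.get("model", ModelParams())
    dyn = config.get("dynamics", DynamicsParams())
    relax_steps = int(config.get("relax_steps", 30_000))
    tracks = config.get("tracks")  # optional explicit CompartmentTrack list
    # radii are compared over the trailing window of the horizon -- the
    # in-silico analogue of imaging treated and control cells at endpoint
    endpoint_fraction = float(config.get("endpoint_fraction", 0.2))
    steps = horizon_steps(hours, n_beads, config.get("scale"))
    stride = max(steps // 40, 1)

    if tracks is None:
        tracks = [
            make_prototype_track(n_beads, het, block_len, seed=derive_seed(seed, 31, t))
            for t in range(n_tracks)
        ]

    rd_ctrl, rd_pert = [], []
    cons_ctrl, cons_pert = [], []
    finals_pert = []
    per_run = []
    flipped_union: list[np.ndarray] = []
    for t, track in enumerate(tracks):
        control_ratio = config.get("control_ratio")
        if control_ratio is None:
            hf = track.h_fraction
            control_ratio = hf / (1.0 - hf)
        for r in range(n_rep):
            s = derive_seed(seed, 40 + t, r)
            start = _relaxed_start(track, params, dyn, s, relax_steps)
            arms = {}
            for arm, ratio in (("control", control_ratio), ("perturbed", perturbed_ratio)):
                proto = Protocol([_production_phase(steps, ratio, stride)])
                # paired design: both arms share the relaxed start *and* the
                # RNG streams (common random numbers), so the percent-change
                # estimate cancels most configurational noise
                traj = run_protocol(start.copy(), params, dyn, proto,
                                    derive_seed(s, 3))
                stats = analysis.domain_radius_series(traj, r_c, min_size)
                arms[arm] = {
                    "rd": stats.steady_state_mean(tail_fraction=endpoint_fraction),
                    "cons": analysis.conservation_fraction(track.marks, traj.marks[-1]),
                    "final_marks": traj.marks[-1].copy(),
                }
            rd_ctrl.append(arms["control"]["rd"])
            rd_pert.append(arms["perturbed"]["rd"])
            cons_ctrl.append(arms["control"]["cons"])
            cons_pert.append(arms["perturbed"]["cons"])
            finals_pert.append(arms["perturbed"]["final_marks"])
            flipped_union.append(
                np.flatnonzero(arms["perturbed"]["final_marks"] != track.marks)
            )
            per_run.append({
                "track": t, "replicate": r, "seed": s,
                "control_ratio": float(control_ratio),
                "rd_control": arms["control"]["rd"],
                "rd_perturbed": arms["perturbed"]["rd"],
                "conservation_control": arms["control"]["cons"],
                "conservation_perturbed": arms["perturbed"]["cons"],
            })

    mean_c, mean_p = float(np.mean(rd_ctrl)), float(np.mean(rd_pert))
    pct_reduction = 100.0 * (1.0 - mean_p / mean_c)

    # ensemble flip statistics on the first track's replicate set
    track0 = tracks[0]
    finals0 = np.stack(finals_pert[: n_rep]) if n_rep > 1 else np.stack(finals_pert[:1])
    flips = analysis.flipping_score(track0.marks, finals0)
    avg_curve = analysis.averaging_curve(track0.marks, finals0)
    enrich = analysis.boundary_enrichment_test(
        track0, np.unique(np.concatenate(flipped_union[: n_rep])),
        seed=derive_seed(seed, 90),
    )

    return {
        "experiment": "perturbation",
        "seed": seed,
        "n_beads": n_beads,
        "steps": steps,
        "perturbed_ratio": perturbed_ratio,
        "mean_rd_control": mean_c,
        "mean_rd_perturbed": mean_p,
        "percent_rd_reduction": pct_reduction,
        "conservation_control": float(np.mean(cons_ctrl)),
        "conservation_perturbed": float(np.mean(cons_pert)),
        "significant_fraction": flips.significant_fraction,
        "averaging_curve": avg_curve.tolist(),
        "boundary_enrichment": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                                 for k, v in enrich.items() if k != "distances_bp"},
        "runs": per_run,
    }


def run_memory_experiment(config: dict) -> dict:
    """Acetylation stimulus for t' then enhanced methylation for t'.

    Phase 1 runs with acetylation:methylation = ``phase1_ac_over_me``
    (default 0.8, the stimulus); phase 2 lowers it (default the value that
    restores the track's initial composition) to model stimulus withdrawal.
    Reports the domain-radius trajectory, conserved/memory/recovered bead
    counts, and optionally a dose-response over phase-1 strengths.
    """
    seed = int(config.get("seed", 0))
    n_beads = int(config.get("n_beads", 300))
    het = float(config.get("het_fraction", 0.6))
    t_prime_h = float(config.get("t_prime_hours", 5.0))
    ac_over_me_1 = float(config.get("phase1_ac_over_me", 0.8))
    ac_over_me_2 = config.get("phase2_ac_over_me")
    n_rep = int(config.get("n_replicates", 3))
    r_c = float(config.get("r_c", 1.8))
    min_size = int(config.get("min_size", 10))
    params = config.get("model", ModelParams())
    dyn = config.get("dynamics", DynamicsParams())
    relax_steps = int(config.get("relax_steps", 30_000))
    dose_values = list(config.get("dose_ac_over_me", []))

    track = make_prototype_track(n_beads, het, seed=derive_seed(seed, 51))
    if ac_over_me_2 is None:
        # restore the initial composition: stationary H fraction = p_me
        ac_over_me_2 = (1.0 - het) / het
    steps_phase = horizon_steps(t_prime_h, n_beads, config.get("scale"))
    stride = max(steps_phase // 20, 1)

    def one_protocol(ratio1):
        return Protocol([
            Phase(n_steps=steps_phase, gamma_ac=ratio1, gamma_me=1.0,
                  frame_stride=stride),
            Phase(n_steps=steps_phase, gamma_ac=float(ac_over_me_2), gamma_me=1.0,
                  frame_stride=stride),
        ])

    def run_arm(ratio1, rep_seed):
        state = _relaxed_start(track, params, dyn, rep_seed, relax_steps)
        traj = run_protocol(state, params, dyn, one_protocol(ratio1), derive_seed(rep_seed, 5))
        kymo = analysis.kymograph(traj)
        mem = analysis.classify_memory(kymo, traj.times, traj.times[0] + steps_phase * dyn.dt_reduced)
        stats = analysis.domain_radius_series(traj, r_c, min_size)
        return mem, stats, traj

    reps = []
    rd_start, rd_tp, rd_end = [], [], []
    for r in range(n_rep):
        mem, stats, traj = run_arm(ac_over_me_1, derive_seed(seed, 70, r))
        reps.append(mem.counts)
        i_tp = int(np.argmin(np.abs(traj.times - (traj.times[0] + steps_phase * dyn.dt_reduced))))
        rd = stats.mean_rd
        rd_start.append(np.nanmean(rd[: max(2, len(rd) // 10)]))
        lo = max(i_tp - 2, 0)
        rd_tp.append(np.nanmean(rd[lo : i_tp + 1]))
        rd_end.append(np.nanmean(rd[-max(2, len(rd) // 10):]))

    dose_rows = []
    for k, ratio1 in enumerate(dose_values):
        counts = []
        for r in range(max(1, n_rep - 1)):
            mem, _, _ = run_arm(ratio1, derive_seed(seed, 80 + k, r))
            counts.append(mem.counts["memory"])
        dose_rows.append({"phase1_ac_over_me": ratio1,
                          "memory_beads": float(np.mean(counts))})

    agg = {k: float(np.mean([c[k] for c in reps]))
           for k in ("conserved", "memory", "recovered", "other")}
    return {
        "experiment": "memory",
        "seed": seed,
        "n_beads": n_beads,
        "steps_per_phase": steps_phase,
        "phase1_ac_over_me": ac_over_me_1,
        "phase2_ac_over_me": float(ac_over_me_2),
        "memory_classes": agg,
        "per_replicate_classes": reps,
        "rd_start": float(np.mean(rd_start)),
        "rd_at_t_prime": float(np.mean(rd_tp)),
        "rd_end": float(np.mean(rd_end)),
        "dose_response": dose_rows,
    }
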