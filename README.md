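# chromkin

Reaction–diffusion simulation of chromatin as a two-state copolymer, with
the analysis stack used to study heterochromatin packing domains:
kymographs, domain radii, flipping scores, memory classes, and Hi-C A/B
compartment calls.

## The problem

Chromatin behaves like a block copolymer of transcriptionally active
euchromatin (E, the A compartment) and repressed heterochromatin (H, the B
compartment).  Two processes shape where the H marks sit: *diffusion* of
marks between spatially neighbouring nucleosome patches (a conserved,
thermal process) and *active rewriting* by histone remodelers — HATs/HDMs
acetylate (H→E, rate Γ_ac) and HMTs/HDACs methylate (E→H, rate Γ_me).
Diffusion alone coarsens heterochromatin without bound (Ostwald ripening);
reactions oppose it, arresting growth at a characteristic domain radius

    R_d ∝ √( (D/Γ_ac) · Γ_me/(Γ_me+Γ_ac) )

`chromkin` implements this model end to end: a beads-on-a-string polymer
(10 kb and 65 nm per bead) with mark-dependent Lennard-Jones interactions
and FENE bonds, overdamped Brownian dynamics (τ_Br = 0.3 s, Δt = 0.01 τ_Br,
so 10⁶ steps ≈ 1 h of real time), Kawasaki-style Metropolis exchange of
marks between beads within 1.8 σ, and stochastic reaction resets with
probabilities p_ac = Γ_ac/(Γ_ac+Γ_me), p_me = 1 − p_ac.  Polymers can be
initialized from ChromHMM-style state BEDs or Hi-C PC1 bedgraphs binarized
at 10 kb, or from synthetic block tracks.  See `docs/methods.md` for the
full model description and parameter table.

It is aimed at chromatin biophysicists and regulatory genomicists who want
to ask how shifts in remodeler activity (drug treatments such as HDAC
inhibition, substrate-stiffness changes, stimulus–withdrawal protocols)
reshape domain size, which genomic positions flip compartment, and how
single-cell changes average away in bulk assays.

## Worked example

```python
import numpy as np
import chromkin as ck
from chromkin.params import Phase, Protocol

# a 300-bead polymer, 60% heterochromatin, in blocks of ~20 beads
track = ck.make_prototype_track(300, 0.6, 20.0, seed=1)
params = ck.ModelParams()
dyn = ck.DynamicsParams()

state = ck.init_conformation(track, params, np.random.default_rng(1))
state, ok = ck.relax(state, params, dyn, max_steps=20_000, seed=1)

# 30 min of real time with the reaction ratio balanced to the composition
proto = Protocol([Phase(n_steps=ck.experiments.horizon_steps(0.5, 300),
                        gamma_ac=1.0, gamma_me=1.5, frame_stride=3000)])
traj = ck.run_protocol(state, params, dyn, proto, seed=2)

stats = ck.domain_radius_series(traj)
print("mean domain radius (sigma):", round(np.nanmean(stats.mean_rd), 2))
print("mark conservation:", round(ck.conservation_fraction(
    traj.marks[0], traj.marks[-1]), 3))
```

Typical output (seed-dependent at the percent level):

```
mean domain radius (sigma): 2.95
mark conservation: 0.89
```

The domain radius is the mean radius of gyration of the spatial clusters of
H beads (≈ 2.95 σ ≈ 190 nm here — a nanoscale packing domain), and the
conservation number says ~89% of 10 kb loci kept their epigenetic identity
over the half hour, the balanced-rate regime in which chromatin identity is
stable.

A `chromkin` command-line tool wraps the same library for shell use:
`chromkin simulate`, `chromkin sweep`, `chromkin analyze`,
`chromkin compartments`, `chromkin fixtures` (see `--help`).

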