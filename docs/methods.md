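# Methods

`chromkin` simulates a two-state chromatin copolymer — euchromatin (E) and
heterochromatin (H) beads on a string — whose epigenetic marks both diffuse
between spatial neighbours (a conserved, thermal Kawasaki exchange) and are
actively rewritten (non-conserved acetylation/methylation reactions).  This
note records the model, the parameter choices and their reasons, the
numerical decisions, and what the synthetic benchmarks do and do not show.

## Model

**Polymer.** N beads, each covering 10 kb of chromatin, diameter
σ = 65 nm.  Consecutive beads are bonded by a FENE spring
(K = 30 kT/σ², R₀ = 1.5 σ, Kremer–Grest values) plus the WCA core of the
pair.  Nonbonded pairs interact through truncated-and-shifted 12-6
Lennard-Jones wells whose depth depends on the mark pair: ε_EE = 0.3,
ε_HH = 1.0, both cut at 2.5 σ; the unlike E–H pair uses ε_EH = 1.0 cut at
2^(1/6) σ, i.e. pure excluded volume.  ε_HH > ε_EE drives heterochromatin
phase separation at kT = 1; ε_HH itself is a package convention (the
governing constraint is only the ordering) and is configurable.  The chain
lives in a reflective cubic box sized from a target bead density of
0.1 σ⁻³ (periodic boundaries are available for sensitivity checks).

**Motion.** Overdamped (position-Langevin) dynamics:
Δx = μF Δt + √(2DΔt) ξ.  The Brownian time τ_Br = 0.3 s is the time for a
bead to diffuse its own diameter in a 150 cP nucleoplasm; we define
D = 1/6 σ²/τ_Br so that 6Dτ_Br = σ², and μ = D/kT.  One *scheduling step*
is Δt = 0.01 τ_Br = 3 ms; 10⁶ steps therefore cover 3000 s ≈ 1 h of real
time.  A single overdamped integrator serves both relaxation and
production: inertia is irrelevant at these scales.

**Mark exchange (diffusion of marks).** Once per scheduling step a random
bead i and a uniformly chosen spatial neighbour j (3D distance < 1.8 σ —
not chain adjacency) propose to swap marks at fixed positions, accepted
with the Metropolis probability min(1, exp(−ΔE/T_E)), T_E = kT by default.
The move conserves the H/E counts exactly and satisfies detailed balance;
it is the microscopic carrier of mark diffusion.  Same-mark proposals cost
ΔE = 0 and are always accepted; they leave the mark field unchanged but
still transport the *tagged label* that the diffusivity estimator tracks
(see below).

**Reactions.** Once per 10³ scheduling steps (≈ 0.3 s⁻¹, in the range of
measured histone-remodeler turnover) a uniformly chosen bead is reset: to E
with probability p_ac = Γ_ac/(Γ_ac+Γ_me), to H otherwise, independent of
its current mark.  This breaks detailed balance; the reaction-only process
is a per-bead reset chain whose stationary H fraction is
Γ_me/(Γ_me+Γ_ac) from any initial condition.  The rates enter only through
p_ac and the cadence, so the single dimensionless control is the ratio
Γ_me/Γ_ac.

**Scaling law.** Diffusion coarsens H domains (Ostwald ripening); the
acetylation reaction converts H inside domains and arrests growth.  The
steady-state domain radius follows

    R_d ∝ sqrt( (D/Γ_ac) · Γ_me/(Γ_me+Γ_ac) )

which `fit_domain_scaling` checks by OLS of measured steady-state radii
against the predictor.  D here is the *effective* mark diffusivity: it is
measured, not set.  `estimate_mark_diffusivity` tags every mark with a
persistent label, records which bead carries which label each frame, and
fits the slope of the label MSD; exchange hops add to the caged bead
motion, so D_eff grows with exchange cadence.

## Numerical choices

* **Substeps.** At Δt = 0.01 τ_Br a plain Euler–Maruyama update is unstable
  for the stiff WCA core (μ·V″·Δt > 1 at typical contact distances), which
  manifests as an over-compressed globule.  Each scheduling step therefore
  integrates motion with 3 equal substeps; exchange/reaction cadences and
  the step↔time mapping are untouched.
* **Force cap.** Nonbonded pair forces are clipped at 60 kT/σ (a soft-core
  regularisation active only below r ≈ 0.94 σ, where the thermal
  penetration probability is already e⁻⁶⁰ᵟ); the FENE bond force is never
  clipped, so bonds cannot creep past R₀.  A substep that would stretch a
  bond past 0.995 R₀ is rejected and retried with a halved displacement
  cap; displacements are additionally capped at 0.35 σ (≈3.5× the per-step
  rms) against rare large noise draws.
* **Precision.** The production kernel works in float32 (positions, forces,
  noise); thermal noise exceeds rounding by ~5 orders of magnitude.  All
  reference implementations used by the test oracles are float64.
* **Neighbor search.** Verlet list at cutoff+0.8 σ skin, rebuilt via a cell
  grid when any bead has moved more than half the skin.
* **RNG.** A hand-rolled PCG32 inside the kernels, seeded per run segment
  with independent sub-streams for motion, exchange and reactions, so a
  cadence change in one process cannot shift another's draws.  Identical
  seed and config reproduce a run bit for bit.
* **Relaxation.** Motion-only dynamics until the block-averaged total
  energy stops decreasing beyond its own sampling noise (2 SE over 8
  samples per block) or a relative tolerance of 10⁻³ — a fluctuating
  equilibrium energy never plateaus pointwise, so the criterion is
  statistical.

## Synthetic tracks and desk scaling

The generator produces single-chromosome E/H block tracks with geometric
block lengths and an exact heterochromatin count.  Two presets recur:

* *Hi-C-like* (A375-style): H:E ratio 0.45 (31% H), E-block mean 60 bins at
  384 beads (35 at 256 beads), giving mean segment lengths of roughly
  0.3–0.5 Mb — the typical A/B compartment segment scale at 10 kb binning.
* *ChromHMM-like* (hMSC-style): 60% H with fine blocks (E-block mean 8
  bins ≈ 80 kb, H-block mean 12 bins ≈ 120 kb), reflecting the much finer
  interleaving of chromatin-state segmentations compared with A/B
  compartment tracks.

Full-scale runs in the source study cover whole chromosomes
(chr19 ≈ 5860 beads at 10 kb) for 2 h of real time (2.4×10⁶ steps).  Desk
runs use a few hundred beads; horizons are scaled by N/5860 so the
*per-bead* exchange and reaction doses match the full-scale conditions.
Problem sizes used by `scripts/acceptance.py`: 300 beads for the
reaction-only composition, 384 beads × 3 seeds for the conservation
experiments, 256 beads × 3 tracks × 2 paired replicates for the
radius-reduction experiments.  These sizes keep the whole script within a
desktop-scale compute envelope while leaving enough beads for 1–4
heterochromatin domains above the 10-bead detection floor.

Two desk-scale caveats matter when comparing with full-scale values:

* A few-hundred-bead polymer condenses its H beads into one or two
  domains, so a much larger fraction of H beads sits on a domain surface
  than at chromosome scale.  Surface beads churn reversibly under
  exchange, which depresses positional mark conservation by several
  percentage points relative to full-scale runs and compresses the gap
  between balanced and hyperacetylated arms.
* With the production reaction cadence (one move per 10³ steps) the
  reaction-limited balance length sqrt(D/Γ_ac) exceeds the polymer size,
  so domain radii saturate at full phase separation regardless of the
  exchange cadence.  The scaling-sweep driver therefore defaults to a
  faster reaction cadence (one move per 25 steps) to place the balance
  length inside the system — the regime the scaling law describes.

## Analysis conventions

* Domains: single-linkage clusters of H beads at r_c = 1.8 σ (the exchange
  neighbourhood), discarding clusters under 10 beads; both equal-domain and
  bead-weighted mean radii are reported.  Radii are in σ (× 65 nm for
  physical units).
* Conservation: fraction of positions whose mark at the final snapshot
  equals the initial track.
* Flipping score: for a bead starting H, +2 × (fraction of replicates
  ending E); starting E, −2 × (fraction ending H).  |score| > 1 (strict)
  marks changes present in a majority of replicates.  The averaging curve
  evaluates the significant fraction over the first k replicates.
* Memory classes use sampled frames: *conserved* = identical at every
  frame; *memory* = changed by 2t′ with the first change in (0, t′];
  *recovered* = back to the initial mark at 2t′ after differing at t′;
  everything else *other*.  Because reversible boundary churn flips marks
  transiently, strict every-frame conservation is rare at desk scales and
  `other` absorbs multi-flip paths; the classes are best read comparatively
  across stimulus strengths.
* Compartment calls: mask rows below 10% of the median coverage,
  observed/expected per diagonal, Pearson correlation, first principal
  component, sign oriented so reference-E bins average positive.  Switches
  require crossing ±0.01 in the treated condition; boundary enrichment uses
  ≥1000-draw permutation nulls.

## Known limitations

Two epigenetic states only; no loop extrusion, lamina tethering, bending
rigidity, explicit bridging proteins, hydrodynamics, or replication.  The
integrator's soft-core cap slightly softens deep-core contacts; exchange
energetics always use the exact potential.  Synthetic tracks emulate block
structure and composition but not the long-range correlation structure of
real PC1 tracks, so tests passing on them demonstrate the machinery and
the model's qualitative regimes, not chromosome-specific predictions.
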