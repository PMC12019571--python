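"""Parameter containers and TOML configuration loading.

All simulation code works in reduced units: the bead diameter sigma is the
length unit, the thermal energy kT is the energy unit, and the Brownian time
tau_Br (the time for a bead to diffuse its own size) is the time unit.  The
physical mapping -- sigma = 65 nm, tau_Br = 0.3 s, one bead = 10 kb -- is
applied only when reading genomic tracks and when reporting results.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field


#: Physical bead diameter in nanometres.
SIGMA_NM = 65.0
#: Physical Brownian time in seconds.
TAU_BR_S = 0.3
#: Genomic span of one bead in base pairs.
BP_PER_BEAD = 10_000

#: WCA cutoff, the minimum of the 12-6 potential.
WCA_CUT = 2.0 ** (1.0 / 6.0)


@dataclass
class ModelParams:
    """Force-field constants of the two-state copolymer.

    Pair interactions are truncated-and-shifted 12-6 Lennard-Jones wells whose
    depth depends on the epigenetic marks of the two beads: like pairs attract
    (eps_HH > eps_EE, driving heterochromatin phase separation) while the
    unlike E-H pair is purely repulsive (WCA).  Consecutive beads are bonded
    with a FENE spring plus the WCA core.
    """

    sigma: float = 1.0
    bp_per_bead: int = BP_PER_BEAD
    eps_EE: float = 0.3
    eps_EH: float = 1.0
    eps_HH: float = 1.0
    cut_attractive: float = 2.5
    cut_repulsive: float = WCA_CUT
    fene_K: float = 30.0
    fene_R0: float = 1.5
    kT: float = 1.0
    density: float = 0.1
    box_side: float | None = None
    boundary_mode: str = "reflective"

    def __post_init__(self) -> None:
        if not (self.eps_HH > self.eps_EE >= 0.0):
            raise ValueError("require eps_HH > eps_EE >= 0")
        if self.cut_attractive <= WCA_CUT:
            raise ValueError("cut_attractive must exceed the WCA minimum 2^(1/6)")
        if self.fene_R0 <= self.sigma:
            raise ValueError("fene_R0 must exceed sigma")
        if self.boundary_mode not in ("reflective", "periodic"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.box_side is not None and self.box_side <= 0:
            raise ValueError("box_side must be positive")

    def box_for(self, n_beads: int) -> float:
        """Box edge: explicit ``box_side`` or from the target bead density."""
        if self.box_side is not None:
            return self.box_side
        return (n_beads / self.density) ** (1.0 / 3.0)

    def eps_matrix(self):
        import numpy as np

        # index 0 = E, 1 = H
        return np.array(
            [[self.eps_EE, self.eps_EH], [self.eps_EH, self.eps_HH]], dtype=np.float64
        )

    def cut_matrix(self):
        import numpy as np

        c_a, c_r = self.cut_attractive, self.cut_repulsive
        return np.array([[c_a, c_r], [c_r, c_a]], dtype=np.float64)


@dataclass
class DynamicsParams:
    """Overdamped (position-Langevin) integrator constants.

    ``tau_br`` anchors the physical timescale: with a 150 cP nucleoplasm and a
    65 nm bead the Stokes-Einstein estimate of the time to diffuse one bead
    diameter is ~0.3 s.  In reduced units the bead diffusivity is 1/6 (so the
    mean-square displacement over one tau_Br is exactly sigma^2) and the
    mobility is D/kT.  One million steps at dt = 0.01 tau_Br cover 3000 s,
    i.e. about an hour of real time.
    """

    tau_br: float = TAU_BR_S
    dt_reduced: float = 0.01
    kT: float = 1.0
    viscosity_cp: float = 150.0
    displacement_cap: float = 0.35
    force_cap: float = 60.0
    n_substeps: int = 3

    #: One scheduling step spans dt_reduced of tau_Br; motion is integrated
    #: with ``n_substeps`` equal substeps for numerical stability of the
    #: stiff excluded-volume core.

    def __post_init__(self) -> None:
        if not (0.0 < self.dt_reduced <= 0.1):
            raise ValueError("dt_reduced must lie in (0, 0.1]")
        if self.tau_br <= 0:
            raise ValueError("tau_br must be positive")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")

    @property
    def d_bead(self) -> float:
        """Bead diffusivity in sigma^2 per tau_Br (MSD = 6 D t)."""
        return 1.0 / 6.0

    @property
    def mobility(self) -> float:
        return self.d_bead / self.kT

    def steps_for_seconds(self, seconds: float) -> int:
        """Number of integration steps covering ``seconds`` of real time."""
        return int(round(seconds / (self.dt_reduced * self.tau_br)))


@dataclass
class KineticsParams:
    """Rates and knobs of the two Monte-Carlo mark processes.

    The exchange (Kawasaki-style diffusion of marks between spatial
    neighbours within ``r_neigh``) is thermal at temperature ``T_E``.  The
    reactions are active resets: a randomly chosen bead becomes E with
    probability p_ac = gamma_ac/(gamma_ac+gamma_me) and H otherwise,
    independent of its current mark, which breaks detailed balance.
    """

    gamma_ac: float = 1.0
    gamma_me: float = 1.0
    T_E: float = 1.0
    r_neigh: float = 1.8

    def __post_init__(self) -> None:
        if self.gamma_ac < 0 or self.gamma_me < 0:
            raise ValueError("rates must be nonnegative")
        if self.r_neigh <= 0:
            raise ValueError("r_neigh must be positive")
        if self.T_E <= 0:
            raise ValueError("T_E must be positive")

    @property
    def p_ac(self) -> float:
        tot = self.gamma_ac + self.gamma_me
        if tot == 0:
            raise ValueError("both reaction rates are zero")
        return self.gamma_ac / tot

    @property
    def p_me(self) -> float:
        return 1.0 - self.p_ac

    @classmethod
    def from_ratio(cls, me_over_ac: float, **kw) -> "KineticsParams":
        """Build from the methylation-to-acetylation rate ratio."""
        return cls(gamma_ac=1.0, gamma_me=float(me_over_ac), **kw)


@dataclass
class Phase:
    """One leg of a protocol: step count, rates and scheduling cadences."""

    n_steps: int
    gamma_ac: float = 0.0
    gamma_me: float = 0.0
    exchange_every: int = 1
    reaction_every: int = 1000
    frame_stride: int = 1000

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if self.exchange_every < 0:  # 0 disables mark exchange
            raise ValueError("exchange_every must be >= 0")
        for name in ("reaction_every", "frame_stride"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.gamma_ac < 0 or self.gamma_me < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class Protocol:
    """Ordered phases executed back to back on one polymer."""

    phases: list[Phase] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")

    @property
    def total_steps(self) -> int:
        return sum(p.n_steps for p in self.phases)


def _apply(cls, table: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(table) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**table)


def load_config(path) -> dict:
    """Read a TOML run configuration.

    Recognised sections: ``[model]``, ``[dynamics]``, ``[kinetics]`` and a
    ``[[protocol.phases]]`` array; anything else is passed through untouched
    so experiment drivers can carry their own settings.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out = dict(raw)
    out["model"] = _apply(ModelParams, raw.get("model", {}))
    out["dynamics"] = _apply(DynamicsParams, raw.get("dynamics", {}))
    out["kinetics"] = _apply(KineticsParams, raw.get("kinetics", {}))
    if "protocol" in raw:
        phases = [_apply(Phase, p) for p in raw["protocol"].get("phases", [])]
        out["protocol"] = Protocol(phases=phases)
    return out


def params_to_json(params) -> str:
    """Serialize any of the parameter dataclasses for run metadata."""
    return json.dumps(dataclasses.asdict(params), sort_keys=True)
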