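"""Genomic track input, synthetic fixtures, initial conformations, and
trajectory round-tripping.

A ``CompartmentTrack`` is a single-chromosome sequence of 10 kb bins, each
binarized to euchromatin (E) or heterochromatin (H).  Tracks come from
ChromHMM-style state BED files (majority-bp vote per bin), from Hi-C PC1
bedgraphs (sign of the mean PC1 per bin), or from the synthetic block
generator used throughout the tests and experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .params import BP_PER_BEAD, ModelParams
from .state import E, H, SimulationState, Trajectory, marks_to_string

TRAJ_FORMAT_VERSION = 1

#: Default ChromHMM 15-state (Broad/Roadmap-style) label mapping.  Active
#: promoter / enhancer / transcribed states go to E; repressed, polycomb,
#: heterochromatin and quiescent states to H.  Fully overridable.
DEFAULT_CHROMHMM_MAP: dict[str, int] = {
    "TssA": E, "TssAFlnk": E, "TxFlnk": E, "Tx": E, "TxWk": E,
    "EnhG": E, "Enh": E, "ZNF/Rpts": E, "Tss": E, "Prom": E,
    "Het": H, "TssBiv": H, "BivFlnk": H, "EnhBiv": H,
    "ReprPC": H, "ReprPCWk": H, "Quies": H, "Repr": H,
}


@dataclass
class BinarizationRule:
    """How raw annotations collapse onto the two-state alphabet.

    BED state labels map through ``chromhmm_state_map`` and each bin takes
    the majority mark by covered bp (ties and uncovered bins fall to the
    ``fill`` mark, H by default -- conservative: unknown sequence stays out
    of the active compartment).  For PC1 bedgraphs the sign of the coverage-
    weighted mean decides: positive means A/E unless ``pc1_positive_is_e``
    is flipped.
    """

    chromhmm_state_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMHMM_MAP)
    )
    pc1_positive_is_e: bool = True
    fill: int = H


@dataclass
class CompartmentTrack:
    """Binned E/H labels along one chromosome (0-based half-open bins)."""

    chrom: str
    marks: np.ndarray
    bin_size: int = BP_PER_BEAD
    start: int = 0
    source: str = "synthetic"
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.marks = np.ascontiguousarray(self.marks, dtype=np.uint8)
        if self.marks.size == 0:
            raise ValueError("track has no bins")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_beads(self) -> int:
        return self.marks.size

    @property
    def h_fraction(self) -> float:
        return float((self.marks == H).mean())

    def bin_interval(self, i: int) -> tuple[int, int]:
        s = self.start + i * self.bin_size
        return s, s + self.bin_size

    def bin_index(self, pos_bp: int) -> int:
        return (pos_bp - self.start) // self.bin_size

    def boundaries_bp(self) -> np.ndarray:
        """Genomic positions (bp) between adjacent bins of unlike marks."""
        change = np.flatnonzero(np.diff(self.marks.astype(np.int8)) != 0)
        return self.start + (change + 1) * self.bin_size


def read_track(
    path,
    format: str,
    rule: BinarizationRule | None = None,
    bin_size: int = BP_PER_BEAD,
) -> CompartmentTrack:
    """Read and rebin a BED state file or PC1 bedgraph into a track.

    ``format`` is ``'bed_states'`` (chrom, start, end, label) or
    ``'bedgraph_pc1'`` (chrom, start, end, value).  Intervals must cover a
    single chromosome; bins with no data take the rule's fill mark and are
    counted in the track notes.
    """
    rule = rule or BinarizationRule()
    if format not in ("bed_states", "bedgraph_pc1"):
        raise ValueError(f"unknown track format {format!r}")
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], usecols=[0, 1, 2, 3],
    )
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"mixed chromosomes {list(chroms)}: single-chromosome tracks only")
    chrom = str(chroms[0])
    lo = int(df["start"].min())
    hi = int(df["end"].max())
    start = (lo // bin_size) * bin_size
    n_bins = -((start - hi) // bin_size)  # ceil((hi - start) / bin_size)

    if format == "bed_states":
        labels = df["value"].astype(str)
        unknown = sorted(set(labels) - set(rule.chromhmm_state_map))
        if unknown:
            raise ValueError(f"unmapped state labels: {unknown}")
        weight = np.zeros((n_bins, 2))  # covered bp voting E/H per bin
    else:
        num = np.zeros(n_bins)  # coverage-weighted PC1 sum
        den = np.zeros(n_bins)

    for row in df.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        b0 = (s - start) // bin_size
        b1 = -((start - e) // bin_size)
        for b in range(b0, b1):
            bs = start + b * bin_size
            ov = min(e, bs + bin_size) - max(s, bs)
            if ov <= 0:
                continue
            if format == "bed_states":
                weight[b, rule.chromhmm_state_map[str(row.value)]] += ov
            else:
                num[b] += ov * float(row.value)
                den[b] += ov

    marks = np.full(n_bins, rule.fill, dtype=np.uint8)
    if format == "bed_states":
        covered = weight.sum(axis=1) > 0
        # majority by covered bp; exact ties go to the fill mark (H)
        maj = np.where(weight[:, H] >= weight[:, E], H, E).astype(np.uint8)
        marks[covered] = maj[covered]
        n_fill = int((~covered).sum())
    else:
        covered = den > 0
        mean_pc1 = np.divide(num, den, out=np.zeros(n_bins), where=covered)
        pos_is_e = rule.pc1_positive_is_e
        sign_marks = np.where(mean_pc1 > 0, E if pos_is_e else H, H if pos_is_e else E)
        marks[covered] = sign_marks[covered].astype(np.uint8)
        n_fill = int((~covered).sum())

    return CompartmentTrack(
        chrom=chrom, marks=marks, bin_size=bin_size, start=start,
        source="chromhmm" if format == "bed_states" else "hic_pc1",
        notes={"n_fill_bins": n_fill, "path": str(path)},
    )


def make_prototype_track(
    n_beads: int,
    het_fraction: float,
    block_mean_len: float = 20.0,
    seed: int = 0,
) -> CompartmentTrack:
    """Synthetic block track: alternating geometric-length H and E blocks.

    E blocks have mean length ``block_mean_len``; H blocks are scaled by the
    odds het_fraction/(1-het_fraction) so the expected H fraction matches.
    The exact H count is then adjusted to round(n_beads * het_fraction) by
    flipping beads at block edges, so the composition is exact.
    """
    if not (0.0 <= het_fraction <= 1.0):
        raise ValueError("het_fraction must lie in [0, 1]")
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if block_mean_len >= n_beads:
        raise ValueError("block_mean_len must be smaller than n_beads")
    rng = np.random.default_rng(seed)
    target_h = int(round(n_beads * het_fraction))
    marks = np.full(n_beads, E, dtype=np.uint8)
    if target_h == 0:
        pass
    elif target_h == n_beads:
        marks[:] = H
    else:
        mean_e = float(block_mean_len)
        mean_h = mean_e * het_fraction / (1.0 - het_fraction)
        cur = H if rng.random() < het_fraction else E
        pos = 0
        while pos < n_beads:
            mean = mean_h if cur == H else mean_e
            length = int(rng.geometric(min(1.0, 1.0 / mean)))
            marks[pos : pos + length] = cur
            pos += length
            cur = E if cur == H else H
        # trim to the exact composition by flipping at block edges
        h_now = int((marks == H).sum())
        while h_now != target_h:
            edges = np.flatnonzero(np.diff(marks.astype(np.int8)) != 0)
            if h_now > target_h:
                cand = [i for i in edges if marks[i] == H] + [i + 1 for i in edges if marks[i + 1] == H]
                i = cand[rng.integers(len(cand))]
                marks[i] = E
                h_now -= 1
            else:
                cand = [i for i in edges if marks[i] == E] + [i + 1 for i in edges if marks[i + 1] == E]
                i = cand[rng.integers(len(cand))]
                marks[i] = H
                h_now += 1
    return CompartmentTrack(
        chrom="synthetic", marks=marks, source="prototype",
        notes={"het_fraction": het_fraction, "block_mean_len": block_mean_len, "seed": seed},
    )


def init_conformation(
    track: CompartmentTrack,
    params: ModelParams,
    rng: np.random.Generator,
    min_sep: float = 0.8,
    max_restarts: int = 50,
) -> SimulationState:
    """Self-avoiding random-walk initial conformation inside the box.

    Each bead is placed one sigma from its predecessor in a uniform random
    direction, resampled while it falls within ``min_sep`` of any earlier
    bead or outside the box.  Grows from the box centre; restarts from
    scratch after too many local failures.
    """
    n = track.n_beads
    box = params.box_for(n)
    sigma = params.sigma
    for _ in range(max_restarts):
        pos = np.empty((n, 3))
        pos[0] = box / 2.0
        ok = True
        for i in range(1, n):
            placed = False
            for _attempt in range(200):
                v = rng.standard_normal(3)
                v *= sigma / np.linalg.norm(v)
                cand = pos[i - 1] + v
                if (cand < 0).any() or (cand > box).any():
                    continue
                d2 = ((pos[: i - 1] - cand) ** 2).sum(axis=1) if i > 1 else np.empty(0)
                if d2.size and d2.min() < (min_sep * sigma) ** 2:
                    continue
                pos[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return SimulationState(positions=pos, marks=track.marks.copy())
    raise RuntimeError(
        f"could not place {n} beads after {max_restarts} restarts; increase the box"
    )


def write_trajectory(traj: Trajectory, path) -> None:
    """Lossless HDF5 dump of frames and metadata (version-tagged)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = TRAJ_FORMAT_VERSION
        fh.attrs["metadata"] = json.dumps(traj.metadata)
        g = fh.create_group("frames")
        g.create_dataset("positions", data=traj.positions.astype(np.float32))
        g.create_dataset("marks", data=traj.marks.astype(np.uint8))
        g.create_dataset("steps", data=traj.steps.astype(np.int64))
        g.create_dataset("times", data=traj.times.astype(np.float64))
        if traj.labels is not None:
            g.create_dataset("labels", data=traj.labels.astype(np.int32))


def read_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("format_version", -1))
        if version != TRAJ_FORMAT_VERSION:
            raise ValueError(
                f"trajectory format version {version} != expected {TRAJ_FORMAT_VERSION}"
            )
        g = fh["frames"]
        return Trajectory(
            positions=g["positions"][...],
            marks=g["marks"][...],
            steps=g["steps"][...],
            times=g["times"][...],
            labels=g["labels"][...] if "labels" in g else None,
            metadata=json.loads(fh.attrs["metadata"]),
        )


def write_xyz(traj: Trajectory, path) -> None:
    """Extended-XYZ export with the mark as a per-atom column."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            fh.write(f'step={int(traj.steps[f])} time={traj.times[f]:.6f} Properties=species:S:1:pos:R:3\n')
            for i in range(traj.n_beads):
                m = "H" if traj.marks[f, i] == H else "E"
                x, y, z = traj.positions[f, i]
                fh.write(f"{m} {x:.5f} {y:.5f} {z:.5f}\n")


def write_track_bed(track: CompartmentTrack, path) -> None:
    with open(path, "w") as fh:
        for i, m in enumerate(track.marks):
            s, e = track.bin_interval(i)
            fh.write(f"{track.chrom}\t{s}\t{e}\t{'H' if m == H else 'E'}\n")


def make_synthetic_contact_matrix(
    track: CompartmentTrack,
    checkerboard_contrast: float = 3.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    decay_exponent: float = 1.0,
) -> np.ndarray:
    """Checkerboard contact-matrix fixture from a track.

    Within-type contacts are ``checkerboard_contrast`` times stronger than
    between-type contacts, modulated by a power-law distance decay
    (1+|i-j|)^-decay_exponent, with multiplicative lognormal noise.
    Symmetric and strictly positive by construction.
    """
    if checkerboard_contrast < 1.0:
        raise ValueError("contrast must be >= 1")
    n = track.n_beads
    rng = np.random.default_rng(seed)
    same = track.marks[:, None] == track.marks[None, :]
    base = np.where(same, checkerboard_contrast, 1.0)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    decay = 1.0 / (1.0 + sep) ** decay_exponent
    mat = base * decay
    if noise_sd > 0:
        noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=(n, n))
        noise = np.sqrt(noise * noise.T)  # keep symmetry
        mat = mat * noise
    np.fill_diagonal(mat, mat.diagonal())
    return (mat + mat.T) / 2.0


def track_summary(track: CompartmentTrack) -> dict:
    return {
        "chrom": track.chrom,
        "n_beads": track.n_beads,
        "bin_size": track.bin_size,
        "h_fraction": track.h_fraction,
        "n_boundaries": int(len(track.boundaries_bp())),
        "source": track.source,
        "marks": marks_to_string(track.marks),
    }
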