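"""Simulation state and trajectory containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Integer codes for the two epigenetic states.
E, H = 0, 1
MARK_CHARS = np.array(["E", "H"])


def marks_from_string(s: str) -> np.ndarray:
    """Decode an 'EHHE...' string into a uint8 mark array."""
    arr = np.frombuffer(s.encode(), dtype="S1")
    out = np.empty(arr.size, dtype=np.uint8)
    out[arr == b"E"] = E
    out[arr == b"H"] = H
    bad = (arr != b"E") & (arr != b"H")
    if bad.any():
        raise ValueError(f"invalid mark characters: {set(arr[bad].tolist())}")
    return out


def marks_to_string(marks: np.ndarray) -> str:
    return "".join(MARK_CHARS[np.asarray(marks, dtype=int)])


@dataclass
class SimulationState:
    """Positions + marks + clocks: everything the dynamics act on.

    Positions are in sigma units; ``sim_time`` is in tau_Br units (multiply by
    ``DynamicsParams.tau_br`` for seconds).  ``labels`` optionally tags each
    mark with a persistent identity that rides along with Kawasaki exchanges,
    used to measure the effective mark diffusivity.
    """

    positions: np.ndarray
    marks: np.ndarray
    step: int = 0
    sim_time: float = 0.0
    rng_seed: int | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.marks = np.ascontiguousarray(self.marks, dtype=np.uint8)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if len(self.marks) != len(self.positions):
            raise ValueError("marks and positions length mismatch")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")

    @property
    def n_beads(self) -> int:
        return len(self.marks)

    @property
    def h_count(self) -> int:
        return int((self.marks == H).sum())

    @property
    def h_fraction(self) -> float:
        return self.h_count / self.n_beads

    def copy(self) -> "SimulationState":
        return SimulationState(
            positions=self.positions.copy(),
            marks=self.marks.copy(),
            step=self.step,
            sim_time=self.sim_time,
            rng_seed=self.rng_seed,
            labels=None if self.labels is None else self.labels.copy(),
        )


@dataclass
class Trajectory:
    """Sampled frames of one run plus the metadata needed to reproduce it."""

    positions: np.ndarray  # (F, N, 3) float32
    marks: np.ndarray  # (F, N) uint8
    steps: np.ndarray  # (F,) int64
    times: np.ndarray  # (F,) float64, tau_Br units
    labels: np.ndarray | None = None  # (F, N) int32, exchange-tracked tags
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.marks) == len(self.steps) == len(self.times)):
            raise ValueError("frame arrays disagree in length")
        if len(self.steps) > 1 and not (np.diff(self.steps) > 0).all():
            raise ValueError("frame steps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    @property
    def n_beads(self) -> int:
        return self.marks.shape[1]

    def frame(self, i: int) -> SimulationState:
        return SimulationState(
            positions=self.positions[i].astype(np.float64),
            marks=self.marks[i],
            step=int(self.steps[i]),
            sim_time=float(self.times[i]),
        )

    def concat(self, other: "Trajectory") -> "Trajectory":
        """Append a later trajectory segment (dropping its duplicate first frame
        if it repeats this trajectory's last step)."""
        j = 1 if other.steps[0] == self.steps[-1] else 0
        lab = None
        if self.labels is not None and other.labels is not None:
            lab = np.concatenate([self.labels, other.labels[j:]])
        return Trajectory(
            positions=np.concatenate([self.positions, other.positions[j:]]),
            marks=np.concatenate([self.marks, other.marks[j:]]),
            steps=np.concatenate([self.steps, other.steps[j:]]),
            times=np.concatenate([self.times, other.times[j:]]),
            labels=lab,
            metadata=dict(self.metadata),
        )
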