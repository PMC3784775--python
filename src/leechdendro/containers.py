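"""Shared data containers for sessions, spike trains, and traces.

Conventions used throughout the package: times in seconds, coordinates in
pixels, firing rates in Hz, covariance in Hz^2.  Spike-time sequences are
strictly ascending per unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Behaviors a semi-intact leech exhibits in the dish.
BEHAVIOR_LABELS = (
    "stationary",
    "crawling",
    "contraction",
    "elongation",
    "swimming",
    "pseudo_swimming",
    "exploring",
    "peristalsis",
)

FUNCTIONAL_CLASSES = ("contractor", "elongator", "intermediate", "inhibitor")

NERVES = ("DP", "MA", "AA", "PP", "RC", "CC")


@dataclass(frozen=True)
class CellIdentity:
    """One identified motoneuron on one root nerve.

    ``cell_type`` is the conventional name of the identified cell (3, L,
    CV, 102, ...), ``side`` the hemiganglion, ``ganglion`` 1 (rostral) or
    2 (caudal) of the exposed pair.  Longitudinal excitors ("contractors",
    cells 3 and L) are recorded on the dorsal-posterior (DP) nerve;
    elongation-related cells (CV, 102, 109) on the medial-anterior (MA)
    nerve.
    """

    cell_type: str
    side: str  # "left" | "right"
    ganglion: int  # 1 (rostral) | 2 (caudal)
    nerve: str
    functional_class: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.ganglion not in (1, 2):
            raise ValueError(f"ganglion must be 1 or 2, got {self.ganglion}")
        if self.nerve not in NERVES:
            raise ValueError(f"unknown nerve {self.nerve!r}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class {self.functional_class!r}")

    @property
    def unit_id(self) -> str:
        """Compact identifier, e.g. ``3_DP_1L`` (cell 3, DP nerve, ganglion 1 left)."""
        return f"{self.cell_type}_{self.nerve}_{self.ganglion}{self.side[0].upper()}"

    @property
    def nerve_id(self) -> str:
        """Nerve/electrode identifier, e.g. ``DP_1L``."""
        return f"{self.nerve}_{self.ganglion}{self.side[0].upper()}"


@dataclass(frozen=True)
class BehaviorInterval:
    t_start: float
    t_end: float
    label: str

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(
                f"interval must have t_start < t_end, got [{self.t_start}, {self.t_end}]"
            )
        if self.label not in BEHAVIOR_LABELS:
            raise ValueError(f"unknown behavior label {self.label!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SpikeTrain:
    """Spike times (s) of one identified unit, strictly ascending."""

    unit: CellIdentity
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(
                f"spike times of unit {self.unit.unit_id} are not strictly ascending"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class KinematicsTrace:
    """Head/tail bead positions on a uniform 25 Hz grid, plus the reference
    point M at the center of the dissected ganglion."""

    t: np.ndarray
    head_xy: np.ndarray  # (n, 2) pixels
    tail_xy: np.ndarray  # (n, 2) pixels
    ref_point_M: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.head_xy = np.asarray(self.head_xy, dtype=float)
        self.tail_xy = np.asarray(self.tail_xy, dtype=float)
        if self.head_xy.shape != (self.t.size, 2) or self.tail_xy.shape != (self.t.size, 2):
            raise ValueError("head_xy and tail_xy must have shape (n_samples, 2)")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if not np.all(dt > 0):
                raise ValueError("time grid must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be uniform")
        if not (np.all(np.isfinite(self.head_xy)) and np.all(np.isfinite(self.tail_xy))):
            raise ValueError("coordinates must be finite")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt


@dataclass
class SuckerTrace:
    """Head/tail sucker attachment booleans on the kinematics grid.

    Joint state coding: 0 both attached, 1 head attached / tail detached,
    2 head detached / tail attached, 3 both detached.
    """

    t: np.ndarray
    head_attached: np.ndarray
    tail_attached: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.head_attached = np.asarray(self.head_attached, dtype=bool)
        self.tail_attached = np.asarray(self.tail_attached, dtype=bool)
        if not (self.t.size == self.head_attached.size == self.tail_attached.size):
            raise ValueError("sucker trace arrays must share one grid")

    @property
    def state(self) -> np.ndarray:
        """Per-sample joint state 0-3."""
        return (~self.head_attached).astype(int) * 2 + (~self.tail_attached).astype(int)


@dataclass(frozen=True)
class TwinEvent:
    """A pair of action potentials on the two connectives interpreted as one
    spike propagating between ganglia.  ``delay_ms`` is (t_caudal −
    t_rostral) in ms; a negative delay means the caudal electrode saw the
    spike first, i.e. the spike traveled tail → head."""

    t_rostral: float
    t_caudal: float

    @property
    def delay_ms(self) -> float:
        return (self.t_caudal - self.t_rostral) * 1000.0

    @property
    def direction(self) -> str:
        return "head_to_tail" if self.delay_ms > 0 else "tail_to_head"


@dataclass
class SyntheticSession:
    """A ground-truth-labeled simulated semi-intact recording."""

    schedule: list[BehaviorInterval]
    kinematics: KinematicsTrace
    suckers: SuckerTrace
    spikes: dict[str, SpikeTrain]  # keyed by unit_id
    connectives: dict[str, np.ndarray]  # {"RC": times, "CC": times}
    truth_twins: list[TwinEvent] = field(default_factory=list)
    config: object | None = None

    @property
    def duration(self) -> float:
        return float(self.schedule[-1].t_end) if self.schedule else 0.0

    def units(self) -> list[CellIdentity]:
        return [st.unit for st in self.spikes.values()]

    def validate(self) -> None:
        """Check the container invariants; raise ValueError on violation."""
        if not self.schedule:
            raise ValueError("empty schedule")
        if abs(self.schedule[0].t_start) > 1e-9:
            raise ValueError("schedule must start at 0")
        for a, b in zip(self.schedule, self.schedule[1:]):
            if abs(a.t_end - b.t_start) > 1e-9:
                raise ValueError(
                    f"schedule gap/overlap between {a.label}@{a.t_end} and {b.label}@{b.t_start}"
                )
        T = self.duration
        seen = set()
        for uid, st in self.spikes.items():
            if uid != st.unit.unit_id:
                raise ValueError(f"spike-train key {uid} != unit id {st.unit.unit_id}")
            key = (st.unit.cell_type, st.unit.side, st.unit.ganglion)
            if key in seen:
                raise ValueError(f"duplicate unit identity {key}")
            seen.add(key)
            if st.times.size and (st.times[0] < 0 or st.times[-1] > T):
                raise ValueError(f"unit {uid} has spikes outside [0, {T}]")


def intervals_with_label(
    schedule: list[BehaviorInterval], label: str
) -> list[BehaviorInterval]:
    return [iv for iv in schedule if iv.label == label]
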