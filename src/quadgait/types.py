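"""Core domain types for quadruped gait analysis.

Conventions used throughout the package: times in seconds, positions in
centimeters, angles in degrees.  Sagittal plane: x is the direction of
travel, y is vertical.  Frame indices are 0-based and time intervals are
half-open ``[contact, next contact)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

#: The four limbs, in the deterministic tie order used when two paws land
#: on the same frame (hindlimbs before forelimbs, left before right).
LIMBS: Tuple[str, ...] = ("LH", "RH", "LF", "RF")
LIMB_TIE_ORDER = {limb: i for i, limb in enumerate(LIMBS)}

HINDLIMBS = ("LH", "RH")
FORELIMBS = ("LF", "RF")

MARKERS: Tuple[str, ...] = ("crest", "hip", "ankle", "toe")

STEP_TYPES = ("plantar", "dorsal")

#: Limb-pair labels for interlimb phase.  "homolateral" couples a hindlimb
#: with the forelimb on the same body side, "heterolateral" with the
#: forelimb on the opposite side.  "swim" is the left-right hindlimb pair
#: during swimming (peak-extension events instead of paw contacts).
PAIRS = ("hindlimb", "forelimb", "homolateral", "heterolateral", "swim")

#: Pairs whose linear phase lives on [0.5, 1] (alternating pairs) versus
#: [0, 0.5] (nominally synchronous pair).
ALTERNATING_PAIRS = ("hindlimb", "forelimb", "homolateral", "swim")
SYNCHRONOUS_PAIRS = ("heterolateral",)


class SchemaError(ValueError):
    """Raised when an input table violates its documented schema."""


@dataclass
class MarkerTrackSet:
    """Per-frame sagittal coordinates of the four markers of one hindlimb.

    ``x`` and ``y`` are (n_frames, 4) arrays with marker columns ordered as
    :data:`MARKERS` (crest, hip, ankle, toe).
    """

    limb: str
    time_s: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.time_s.shape[0]
        if self.x.shape != (n, 4) or self.y.shape != (n, 4):
            raise ValueError(
                f"marker arrays must be (n_frames, 4); got x{self.x.shape} y{self.y.shape}"
            )
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite marker coordinates")

    @property
    def n_frames(self) -> int:
        return int(self.time_s.shape[0])

    def marker(self, name: str) -> np.ndarray:
        """Return an (n_frames, 2) array of one marker's coordinates."""
        j = MARKERS.index(name)
        return np.column_stack([self.x[:, j], self.y[:, j]])


@dataclass
class JointAngleSeries:
    """Per-frame proximal (hip) and distal (ankle) joint angles, degrees."""

    limb: str
    time_s: np.ndarray
    proximal_deg: np.ndarray
    distal_deg: np.ndarray
    #: frames excluded because a zero-length segment made the angle undefined
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.proximal_deg = np.asarray(self.proximal_deg, dtype=float)
        self.distal_deg = np.asarray(self.distal_deg, dtype=float)
        if self.excluded is None:
            self.excluded = np.zeros(self.time_s.shape, dtype=bool)
        if not (
            self.time_s.shape == self.proximal_deg.shape == self.distal_deg.shape
        ):
            raise ValueError("angle series length mismatch")

    def __len__(self) -> int:
        return int(self.time_s.shape[0])


@dataclass(frozen=True)
class StepCycle:
    """One limb's stride: initial contact to the next initial contact."""

    limb: str
    contact_s: float
    liftoff_s: float
    next_contact_s: float
    stride_distance_cm: float
    step_type: str = "plantar"

    def __post_init__(self) -> None:
        if not (self.contact_s < self.liftoff_s < self.next_contact_s):
            raise ValueError(
                "step cycle requires contact < liftoff < next contact "
                f"({self.contact_s}, {self.liftoff_s}, {self.next_contact_s})"
            )
        if self.step_type not in STEP_TYPES:
            raise ValueError(f"unknown step_type {self.step_type!r}")

    @property
    def stance_s(self) -> float:
        return self.liftoff_s - self.contact_s

    @property
    def swing_s(self) -> float:
        return self.next_contact_s - self.liftoff_s

    @property
    def stride_s(self) -> float:
        return self.next_contact_s - self.contact_s

    @property
    def duty_cycle(self) -> float:
        return self.stance_s / self.stride_s

    @property
    def stride_frequency_hz(self) -> float:
        return 1.0 / self.stride_s

    @property
    def instantaneous_speed_cm_s(self) -> float:
        return self.stride_distance_cm / self.stride_s


@dataclass(frozen=True)
class PhaseObservation:
    """One interlimb (or swim) phase value tied to a reference stride."""

    pair: str
    raw_phase: float
    linear_phase: float
    reference_index: int
    step_type: str = "plantar"
    multi_step: bool = False
    irregular: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.pair not in PAIRS:
            raise ValueError(f"unknown pair {self.pair!r}")
        if not (0.0 <= self.raw_phase < 1.0):
            raise ValueError(f"raw_phase {self.raw_phase} outside [0, 1)")


@dataclass(frozen=True)
class IrregularityThreshold:
    """Control mean +/- 2 SD bounds on the linear phase scale."""

    pair: str
    control_mean: float
    control_sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.control_sd <= 0:
            raise ValueError("control_sd must be positive")
        if not self.lower < self.upper:
            raise ValueError("threshold bounds out of order")

    def contains(self, value: float) -> bool:
        """True if *value* is within control variability (boundary inclusive:
        only values strictly beyond 2 SD count as irregular)."""
        return self.lower <= value <= self.upper


def wrap_unit(x):
    """Wrap values onto the circular unit interval [0, 1)."""
    return np.mod(x, 1.0)


def circular_distance(a: float, b: float) -> float:
    """Shortest distance between two points on the unit circle (<= 0.5)."""
    d = abs((a - b) % 1.0)
    return min(d, 1.0 - d)
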