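"""Schedule specifications, chamber geometry, and event-stream generation.

A time-based (noncontingent) schedule delivers water on a timer, independent
of the animal's behavior.  The time component is either fixed (FT: every
``mean_interval`` seconds) or variable (VT: intervals drawn from a
constant-probability list averaging ``mean_interval``).  The space component
determines whether every delivery uses one dispenser (fixed space) or a
uniformly random one of the four wall dispensers (variable space).
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeType",
    "SpaceType",
    "Phase",
    "ScheduleSpec",
    "ChamberGeometry",
    "VT_INTERVALS",
    "generate_intervals",
    "assign_dispensers",
    "default_design",
    "subject_seed_sequence",
]

#: The seven-value constant-probability interval list (seconds); mean 30 s.
VT_INTERVALS: tuple[float, ...] = (3.0, 7.0, 13.0, 21.0, 31.0, 47.0, 88.0)


class TimeType(str, enum.Enum):
    FT = "FT"
    VT = "VT"
    NONE = "NONE"


class SpaceType(str, enum.Enum):
    FIXED = "FIXED"
    VARIABLE = "VARIABLE"
    NA = "NA"


class Phase(str, enum.Enum):
    SCHEDULE = "SCHEDULE"
    EXTINCTION = "EXTINCTION"


class NoScheduleError(ValueError):
    """Raised when event generation is requested for a no-schedule spec."""


@dataclass(frozen=True)
class ScheduleSpec:
    """One schedule condition: a time component crossed with a space component.

    Parameters
    ----------
    time_type
        FT (constant interval), VT (variable interval), or NONE (extinction:
        no deliveries, no tones).
    space_type
        FIXED (all deliveries at ``fixed_dispenser``), VARIABLE (uniform over
        the four dispensers), or NA for the no-schedule condition.
    mean_interval
        Mean inter-delivery interval in seconds.
    vt_intervals
        Interval list used under VT; must average ``mean_interval``.
    fixed_dispenser
        Dispenser index 0-3 used under fixed space.
    tone_lead
        Seconds of signalling tone immediately before each delivery.
    access_duration
        Seconds of water access following each delivery.
    """

    time_type: TimeType
    space_type: SpaceType
    mean_interval: float = 30.0
    vt_intervals: tuple[float, ...] = VT_INTERVALS
    fixed_dispenser: int = 0
    tone_lead: float = 3.0
    access_duration: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.fixed_dispenser <= 3:
            raise ValueError(f"dispenser index must be 0-3, got {self.fixed_dispenser}")
        if self.time_type is TimeType.VT:
            mean = float(np.mean(self.vt_intervals))
            if abs(mean - self.mean_interval) > 1e-9:
                raise ValueError(
                    f"VT interval list mean {mean} != mean_interval {self.mean_interval}"
                )
        if self.time_type is TimeType.NONE and self.space_type is not SpaceType.NA:
            raise ValueError("time_type NONE requires space_type NA")

    @property
    def label(self) -> str:
        if self.time_type is TimeType.NONE:
            return "NONE"
        return f"{self.time_type.value}-{self.space_type.value}"


#: The no-schedule (extinction) condition.
EXTINCTION_SPEC = ScheduleSpec(time_type=TimeType.NONE, space_type=SpaceType.NA)


@dataclass(frozen=True)
class ChamberGeometry:
    """Square open-field chamber with one dipper at the midpoint of each wall.

    The floor is partitioned into a ``zone_rows`` x ``zone_cols`` grid of equal
    cells for occupancy statistics.  Dispenser order: 0 south (y=0), 1 east,
    2 north, 3 west.
    """

    width: float = 92.0
    length: float = 92.0
    dispenser_radius: float = 6.0
    zone_rows: int = 10
    zone_cols: int = 10

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("chamber dimensions must be positive")
        if self.zone_rows < 1 or self.zone_cols < 1:
            raise ValueError("zone grid must be at least 1x1")
        if self.dispenser_radius <= 0 or self.dispenser_radius > min(self.width, self.length) / 2:
            raise ValueError("dispenser_radius inconsistent with chamber size")

    @property
    def dispenser_positions(self) -> np.ndarray:
        """(4, 2) array of dispenser (x, y) at the wall midpoints."""
        w, l = self.width, self.length
        return np.array(
            [[w / 2, 0.0], [w, l / 2], [w / 2, l], [0.0, l / 2]], dtype=float
        )

    @property
    def n_zones(self) -> int:
        return self.zone_rows * self.zone_cols

    def zone_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Map coordinates to flat zone indices.

        Cells are half-open [lo, hi) with the top/right chamber edge closed,
        so every in-bounds point bins deterministically.
        """
        cell_w = self.width / self.zone_cols
        cell_l = self.length / self.zone_rows
        cx = np.clip(np.floor(np.asarray(x) / cell_w).astype(int), 0, self.zone_cols - 1)
        cy = np.clip(np.floor(np.asarray(y) / cell_l).astype(int), 0, self.zone_rows - 1)
        return cy * self.zone_cols + cx


def generate_intervals(
    spec: ScheduleSpec, session_length: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw inter-delivery intervals and return cumulative delivery times.

    FT draws are all equal to ``spec.mean_interval``; VT draws are uniform
    picks with replacement from ``spec.vt_intervals`` (the constant-probability
    property of the list is what makes the momentary delivery rate flat).
    Times are truncated at ``session_length`` (a delivery exactly at the end
    of the session is kept).
    """
    if spec.time_type is TimeType.NONE:
        raise NoScheduleError("no schedule to generate: time_type is NONE")
    if session_length <= 0:
        raise ValueError("session_length must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if spec.time_type is TimeType.FT:
        n = int(session_length // spec.mean_interval)
        return spec.mean_interval * np.arange(1, n + 1)
    # VT: draw until the cumulative time exceeds the session.
    times: list[float] = []
    t = 0.0
    intervals = np.asarray(spec.vt_intervals, dtype=float)
    while True:
        t += float(rng.choice(intervals))
        if t > session_length:
            break
        times.append(t)
    return np.asarray(times, dtype=float)


def assign_dispensers(
    delivery_times: np.ndarray, spec: ScheduleSpec, seed: int | np.random.Generator
) -> np.ndarray:
    """Assign a dispenser index to each delivery.

    Fixed space: all deliveries at ``spec.fixed_dispenser``.  Variable space:
    i.i.d. uniform over the four dispensers.
    """
    n = len(delivery_times)
    if n == 0:
        return np.empty(0, dtype=int)
    if spec.space_type is SpaceType.FIXED:
        return np.full(n, spec.fixed_dispenser, dtype=int)
    if spec.space_type is SpaceType.VARIABLE:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        return rng.integers(0, 4, size=n)
    raise ValueError(f"cannot assign dispensers under space_type {spec.space_type}")


def default_design() -> list[tuple[str, ScheduleSpec]]:
    """The 12-subject, 3-per-condition design of the original experiment.

    S1-S3 fixed space / fixed time, S4-S6 fixed space / variable time,
    S7-S9 variable space / fixed time, S10-S12 variable space / variable time.
    """
    conditions = [
        (SpaceType.FIXED, TimeType.FT),
        (SpaceType.FIXED, TimeType.VT),
        (SpaceType.VARIABLE, TimeType.FT),
        (SpaceType.VARIABLE, TimeType.VT),
    ]
    design = []
    i = 1
    for space, time in conditions:
        for _ in range(3):
            design.append((f"S{i}", ScheduleSpec(time_type=time, space_type=space)))
            i += 1
    return design


def subject_seed_sequence(
    master_seed: int, subject_id: str, phase: Phase, session_index: int
) -> np.random.SeedSequence:
    """Stable per-session seed derivation.

    The subject id is folded in through CRC-32 so that any subset of sessions
    can be regenerated independently of the rest of the experiment.
    """
    subj_key = zlib.crc32(subject_id.encode("utf-8"))
    phase_key = 1 if phase is Phase.SCHEDULE else 2
    return np.random.SeedSequence([master_seed, subj_key, phase_key, session_index])
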