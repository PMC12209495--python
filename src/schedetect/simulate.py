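"""Synthetic open-field chamber sessions with condition-dependent locomotion.

The generative model is deliberately simple: a two-state (dwell / explore)
switching random walk with Gaussian step noise and reflecting walls.  While a
delivery is signalled (tone) and during water access the agent is pulled
toward the active dispenser; between deliveries it alternates between
exploring the chamber and dwelling near an "expected" dispenser — the fixed
one under fixed-space schedules, a randomly chosen one under variable-space
schedules, and (rarely) a random one under extinction.  Head entries fire as
a thinned Poisson process while the agent is inside a dispenser's detection
radius.

None of this models real rat kinematics; it produces the statistical
structure the downstream analysis presumes — concentrated occupancy under
fixed-space schedules, multi-focus occupancy under variable space, diffuse
occupancy and few head entries under extinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .schedules import (
    EXTINCTION_SPEC,
    ChamberGeometry,
    Phase,
    ScheduleSpec,
    SpaceType,
    TimeType,
    assign_dispensers,
    default_design,
    generate_intervals,
    subject_seed_sequence,
)

__all__ = [
    "LocomotionParams",
    "TrajectorySession",
    "simulate_session",
    "simulate_experiment",
    "DT",
    "SESSION_LENGTH",
]

#: Sampling period of the position tracker, seconds.
DT = 0.2
#: Session length, seconds (20 minutes -> 6,000 samples).
SESSION_LENGTH = 1200.0


@dataclass(frozen=True)
class LocomotionParams:
    """Movement-model parameters (all rates per second, lengths in cm).

    ``dwell_rate`` / ``leave_rate`` govern the explore->dwell and
    dwell->explore transitions; ``approach_gain`` is the exponential pull
    toward the current goal; ``step_noise_explore``/``step_noise_dwell`` are
    per-step Gaussian SDs; ``entry_rate`` is the head-entry hazard while
    inside a dispenser's detection radius.
    """

    dwell_rate: float = 0.12
    leave_rate: float = 0.10
    approach_gain: float = 2.5
    step_noise_explore: float = 3.0
    step_noise_dwell: float = 1.0
    entry_rate: float = 0.8

    def __post_init__(self) -> None:
        if min(self.dwell_rate, self.leave_rate, self.approach_gain, self.entry_rate) < 0:
            raise ValueError("rates and gains must be nonnegative")
        if self.step_noise_explore < 0 or self.step_noise_dwell < 0:
            raise ValueError("step-noise scales must be nonnegative")

    @classmethod
    def defaults_for(cls, spec: ScheduleSpec) -> "LocomotionParams":
        """Condition defaults: motivated dwelling under a schedule, mostly
        exploration and sparse entries under extinction."""
        if spec.time_type is TimeType.NONE:
            return cls(dwell_rate=0.02, leave_rate=0.25, entry_rate=0.15)
        return cls()


@dataclass(frozen=True)
class TrajectorySession:
    """One subject-session: tracked positions plus discrete event logs.

    ``samples`` is an (n, 3) float array of (t, x, y) rows at 0.2-s spacing;
    ``head_entries`` and ``deliveries`` are (m, 2) arrays of (t, dispenser).
    """

    subject_id: str
    phase: Phase
    session_index: int
    schedule: ScheduleSpec
    samples: np.ndarray
    head_entries: np.ndarray
    deliveries: np.ndarray

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (t, x, y)")
        if self.session_index < 1:
            raise ValueError("session_index is 1-based")
        for name in ("head_entries", "deliveries"):
            ev = getattr(self, name)
            if ev.size and np.any(np.diff(ev[:, 0]) < 0):
                raise ValueError(f"{name} must be nondecreasing in t")

    @property
    def times(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:3]


def _reflect(v: float, hi: float) -> float:
    """Reflect a coordinate into [0, hi] (repeatedly, for large excursions)."""
    while v < 0.0 or v > hi:
        if v < 0.0:
            v = -v
        else:
            v = 2.0 * hi - v
    return v


def simulate_session(
    spec: ScheduleSpec,
    geom: ChamberGeometry,
    params: LocomotionParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "S0",
    phase: Phase | None = None,
    session_index: int = 1,
    session_length: float = SESSION_LENGTH,
) -> TrajectorySession:
    """Simulate one session under a schedule spec.

    Any integer seed (or a SeedSequence) is accepted.  The returned session
    has exactly ``session_length / DT`` samples starting at t = 0.
    """
    if params is None:
        params = LocomotionParams.defaults_for(spec)
    if phase is None:
        phase = Phase.EXTINCTION if spec.time_type is TimeType.NONE else Phase.SCHEDULE
    rng = np.random.default_rng(seed)
    n_steps = int(round(session_length / DT))
    disp = geom.dispenser_positions

    # Event streams. Under NONE there are no tones or deliveries.
    if spec.time_type is TimeType.NONE:
        delivery_times = np.empty(0)
        delivery_disp = np.empty(0, dtype=int)
    else:
        delivery_times = generate_intervals(spec, session_length, rng)
        delivery_disp = assign_dispensers(delivery_times, spec, rng)

    # Per-step goal: -1 none, else dispenser index active during the tone
    # lead and the access window of each delivery.
    goal_of_step = np.full(n_steps, -1, dtype=int)
    for t_del, d in zip(delivery_times, delivery_disp):
        lo = max(0, int(math.ceil((t_del - spec.tone_lead) / DT)))
        hi = min(n_steps, int(math.floor((t_del + spec.access_duration) / DT)) + 1)
        goal_of_step[lo:hi] = d

    # Pre-drawn randomness keeps the Python loop cheap.
    noise = rng.standard_normal((n_steps, 2))
    u_switch = rng.random(n_steps)
    u_entry = rng.random(n_steps)
    u_target = rng.integers(0, 4, size=n_steps)

    p_dwell = 1.0 - math.exp(-params.dwell_rate * DT)
    p_leave = 1.0 - math.exp(-params.leave_rate * DT)
    pull = 1.0 - math.exp(-params.approach_gain * DT)
    p_entry = 1.0 - math.exp(-params.entry_rate * DT)
    r2 = geom.dispenser_radius**2

    w, l = geom.width, geom.length
    x, y = w / 2.0, l / 2.0  # start at chamber center
    dwelling = False
    dwell_target = spec.fixed_dispenser if spec.space_type is SpaceType.FIXED else 0

    xy = np.empty((n_steps, 2))
    entries: list[tuple[float, int]] = []

    for i in range(n_steps):
        g = goal_of_step[i]
        if g >= 0:
            # signalled delivery: approach the active dispenser
            tx, ty = disp[g]
            x += pull * (tx - x) + params.step_noise_dwell * noise[i, 0]
            y += pull * (ty - y) + params.step_noise_dwell * noise[i, 1]
        elif dwelling:
            if u_switch[i] < p_leave:
                dwelling = False
            tx, ty = disp[dwell_target]
            x += pull * (tx - x) + params.step_noise_dwell * noise[i, 0]
            y += pull * (ty - y) + params.step_noise_dwell * noise[i, 1]
        else:
            if u_switch[i] < p_dwell:
                dwelling = True
                if spec.space_type is SpaceType.FIXED:
                    dwell_target = spec.fixed_dispenser
                else:
                    dwell_target = int(u_target[i])
            x += params.step_noise_explore * noise[i, 0]
            y += params.step_noise_explore * noise[i, 1]
        x = _reflect(x, w)
        y = _reflect(y, l)
        xy[i, 0] = x
        xy[i, 1] = y
        if u_entry[i] < p_entry:
            # head entry only registers inside a detection radius
            d2 = (disp[:, 0] - x) ** 2 + (disp[:, 1] - y) ** 2
            nearest = int(np.argmin(d2))
            if d2[nearest] <= r2:
                entries.append((i * DT, nearest))

    t = np.arange(n_steps) * DT
    samples = np.column_stack([t, xy])
    head_entries = (
        np.array(entries, dtype=float) if entries else np.empty((0, 2))
    )
    deliveries = (
        np.column_stack([delivery_times, delivery_disp.astype(float)])
        if delivery_times.size
        else np.empty((0, 2))
    )
    return TrajectorySession(
        subject_id=subject_id,
        phase=phase,
        session_index=session_index,
        schedule=spec,
        samples=samples,
        head_entries=head_entries,
        deliveries=deliveries,
    )


def simulate_experiment(
    design: list[tuple[str, ScheduleSpec]] | None = None,
    n_schedule_sessions: int = 30,
    n_extinction_sessions: int = 10,
    seed: int = 0,
    geom: ChamberGeometry | None = None,
    params_for: "callable | None" = None,
) -> list[TrajectorySession]:
    """Simulate a full experiment: per subject, schedule sessions then
    extinction sessions, with per-session seeds derived from the master seed.

    ``design`` defaults to the 12-subject, 3-per-condition layout.
    ``params_for(spec)`` may override the locomotion defaults per condition.
    """
    if design is None:
        design = default_design()
    if n_schedule_sessions <= 0 or n_extinction_sessions < 0:
        raise ValueError("session counts must be positive (extinction >= 0)")
    ids = [sid for sid, _ in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in design")
    if geom is None:
        geom = ChamberGeometry()
    if params_for is None:
        params_for = LocomotionParams.defaults_for

    sessions: list[TrajectorySession] = []
    for subject_id, spec in design:
        for k in range(1, n_schedule_sessions + 1):
            ss = subject_seed_sequence(seed, subject_id, Phase.SCHEDULE, k)
            sessions.append(
                simulate_session(
                    spec, geom, params_for(spec), ss,
                    subject_id=subject_id, phase=Phase.SCHEDULE, session_index=k,
                )
            )
        for k in range(1, n_extinction_sessions + 1):
            ss = subject_seed_sequence(seed, subject_id, Phase.EXTINCTION, k)
            sessions.append(
                simulate_session(
                    EXTINCTION_SPEC, geom, params_for(EXTINCTION_SPEC), ss,
                    subject_id=subject_id, phase=Phase.EXTINCTION, session_index=k,
                )
            )
    return sessions
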