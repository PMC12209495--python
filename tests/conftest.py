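import numpy as np
import pytest

from schedetect import (
    ChamberGeometry,
    Phase,
    ScheduleSpec,
    SpaceType,
    TimeType,
    TrajectorySession,
    feature_table,
    simulate_experiment,
)
from schedetect.schedules import EXTINCTION_SPEC
from schedetect.simulate import DT


@pytest.fixture(scope="session")
def geom() -> ChamberGeometry:
    return ChamberGeometry()


def make_session(
    xy: np.ndarray,
    head_entries: np.ndarray | None = None,
    deliveries: np.ndarray | None = None,
    spec: ScheduleSpec | None = None,
    subject_id: str = "S0",
    phase: Phase = Phase.SCHEDULE,
    session_index: int = 1,
) -> TrajectorySession:
    """Build a session from explicit coordinates (t implied at 0.2-s spacing)."""
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) * DT
    return TrajectorySession(
        subject_id=subject_id,
        phase=phase,
        session_index=session_index,
        schedule=spec or EXTINCTION_SPEC,
        samples=np.column_stack([t, xy]),
        head_entries=np.asarray(head_entries, dtype=float).reshape(-1, 2)
        if head_entries is not None
        else np.empty((0, 2)),
        deliveries=np.asarray(deliveries, dtype=float).reshape(-1, 2)
        if deliveries is not None
        else np.empty((0, 2)),
    )


@pytest.fixture(scope="session")
def small_experiment(geom):
    """A reduced synthetic experiment: 12 subjects x (8 schedule + 7
    extinction) sessions, enough to exercise the exclusion rules (>5
    sessions per phase) while staying fast."""
    return simulate_experiment(
        n_schedule_sessions=8, n_extinction_sessions=7, seed=7, geom=geom
    )


@pytest.fixture(scope="session")
def small_features(small_experiment, geom):
    return feature_table(small_experiment, geom)
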