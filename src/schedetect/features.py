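"""Per-session spatiotemporal measures.

Eight measures summarize a session: head-entry counts at each of the four
dispensers, total traveled distance, the standard deviation of frame-by-frame
speed, the Shannon entropy of the time-in-zone distribution over the 10x10
chamber partition, and the Kullback-Leibler divergence of that distribution
from the preceding session's.  Two optional temporal measures (mean and SD of
the interresponse time between head entries) can be appended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedules import ChamberGeometry
from .simulate import DT, TrajectorySession

__all__ = [
    "OccupancyGrid",
    "FeatureVector",
    "FEATURE_COLUMNS",
    "IRT_COLUMNS",
    "occupancy_grid",
    "location_entropy",
    "divergence",
    "traveled_distance",
    "speed_series",
    "speed_sd",
    "head_entry_counts",
    "irt_features",
    "session_features",
    "feature_table",
]

log = logging.getLogger(__name__)

#: Column order of the eight-measure feature block.
FEATURE_COLUMNS = (
    "entries_d0", "entries_d1", "entries_d2", "entries_d3",
    "traveled_distance", "speed_sd", "location_entropy", "divergence",
)
IRT_COLUMNS = ("irt_mean", "irt_sd")


class DivergenceUndefinedError(ValueError):
    """Some cell has P > 0 where Q = 0 and no smoothing was requested."""


@dataclass(frozen=True)
class OccupancyGrid:
    """Standardized time-in-zone distribution over the chamber partition."""

    proportions: np.ndarray  # (rows, cols), sums to 1
    total_time: float

    def __post_init__(self) -> None:
        p = self.proportions
        if np.any(p < 0):
            raise ValueError("occupancy proportions must be nonnegative")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError("occupancy proportions must sum to 1")


@dataclass(frozen=True)
class FeatureVector:
    entries: tuple[int, int, int, int]
    traveled_distance: float
    speed_sd: float
    location_entropy: float
    divergence: float
    irt_mean: float | None = None
    irt_sd: float | None = None
    irt_imputed: bool = False

    def as_dict(self, include_irt: bool = False) -> dict[str, float]:
        d = {
            "entries_d0": self.entries[0],
            "entries_d1": self.entries[1],
            "entries_d2": self.entries[2],
            "entries_d3": self.entries[3],
            "traveled_distance": self.traveled_distance,
            "speed_sd": self.speed_sd,
            "location_entropy": self.location_entropy,
            "divergence": self.divergence,
        }
        if include_irt:
            d["irt_mean"] = self.irt_mean
            d["irt_sd"] = self.irt_sd
        return d


def occupancy_grid(session: TrajectorySession, geom: ChamberGeometry) -> OccupancyGrid:
    """Accumulate one sample period of time per sample into its zone cell and
    normalize by total session time."""
    if session.samples.shape[0] == 0:
        raise ValueError("empty session")
    xy = session.xy
    if np.any(xy < 0) or np.any(xy[:, 0] > geom.width) or np.any(xy[:, 1] > geom.length):
        raise ValueError("samples out of chamber bounds")
    idx = geom.zone_index(xy[:, 0], xy[:, 1])
    counts = np.bincount(idx, minlength=geom.n_zones).astype(float)
    time_per_cell = counts * DT
    total = float(time_per_cell.sum())
    return OccupancyGrid(
        proportions=(time_per_cell / total).reshape(geom.zone_rows, geom.zone_cols),
        total_time=total,
    )


def location_entropy(grid: OccupancyGrid) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 := 0."""
    p = grid.proportions[grid.proportions > 0]
    return float(-(p * np.log(p)).sum())


def _smooth(p: np.ndarray, total_time: float, pseudo_time: float) -> np.ndarray:
    """Re-normalize after adding pseudo-time to every cell."""
    t = p * total_time + pseudo_time
    return t / t.sum()


def divergence(
    p: OccupancyGrid, q: OccupancyGrid, smoothing: float = DT
) -> float:
    """Kullback-Leibler divergence D(P || Q) in nats.

    Cells with P = 0 contribute zero.  With ``smoothing`` > 0 (seconds of
    pseudo-occupancy added to every cell of both grids before normalizing)
    the result is always finite; with smoothing 0 the strict support
    condition applies and P > 0 on a Q-null cell raises.
    """
    if p.proportions.shape != q.proportions.shape:
        raise ValueError("grids have different shapes")
    if smoothing < 0:
        raise ValueError("smoothing must be nonnegative")
    if smoothing > 0:
        pp = _smooth(p.proportions, p.total_time, smoothing)
        qq = _smooth(q.proportions, q.total_time, smoothing)
    else:
        pp, qq = p.proportions, q.proportions
        if np.any((pp > 0) & (qq == 0)):
            raise DivergenceUndefinedError(
                "divergence undefined: P has mass where Q is zero (no smoothing)"
            )
    mask = pp > 0
    return float((pp[mask] * (np.log(pp[mask]) - np.log(qq[mask]))).sum())


def traveled_distance(session: TrajectorySession) -> float:
    """Total path length: sum of Euclidean distances between consecutive
    samples.  A single-sample session has distance 0 by convention."""
    xy = session.xy
    if xy.shape[0] < 2:
        log.warning("traveled_distance on a <2-sample session: returning 0")
        return 0.0
    return float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())


def speed_series(session: TrajectorySession, variant: str = "padded") -> np.ndarray:
    """Frame-by-frame speeds (cm/s) at the tracker's 5-Hz resolution.

    ``variant="padded"`` (default) sets v_0 := v_1 so the series length
    equals the sample count; ``variant="diff"`` returns the n-1 raw
    differences.
    """
    xy = session.xy
    if xy.shape[0] < 2:
        raise ValueError("speed series needs at least 2 samples")
    v = np.linalg.norm(np.diff(xy, axis=0), axis=1) / DT
    if variant == "diff":
        return v
    if variant == "padded":
        return np.concatenate([[v[0]], v])
    raise ValueError(f"unknown speed-series variant: {variant}")


def speed_sd(session: TrajectorySession, variant: str = "padded") -> float:
    """Population SD of the speed series (divisor n)."""
    return float(np.std(speed_series(session, variant)))


def head_entry_counts(session: TrajectorySession) -> tuple[int, int, int, int]:
    """Number of head entries at each of the four dispensers."""
    if session.head_entries.size == 0:
        return (0, 0, 0, 0)
    d = session.head_entries[:, 1].astype(int)
    counts = np.bincount(d, minlength=4)
    return tuple(int(c) for c in counts[:4])


def irt_features(
    session: TrajectorySession, session_length: float | None = None
) -> tuple[float, float, bool]:
    """Mean and SD of interresponse times between successive head entries,
    pooled across dispensers.

    With fewer than two entries the IRT is undefined; the mean is imputed to
    the session length (preserving "a long time between responses") and the
    SD to 0.  Returns (mean, sd, imputed_flag).
    """
    if session_length is None:
        session_length = float(session.times[-1]) + DT if session.times.size else 0.0
    t = session.head_entries[:, 0] if session.head_entries.size else np.empty(0)
    if t.size < 2:
        return float(session_length), 0.0, True
    irts = np.diff(t)
    return float(irts.mean()), float(np.std(irts)), False


def session_features(
    session: TrajectorySession,
    previous_session: TrajectorySession | None,
    geom: ChamberGeometry,
    smoothing: float = DT,
    include_irt: bool = False,
    speed_variant: str = "padded",
) -> FeatureVector:
    """Assemble the full feature vector for one session.

    Divergence is computed against the previous session's occupancy grid; a
    session without a predecessor (the subject's very first) is compared with
    itself, giving divergence 0.
    """
    grid = occupancy_grid(session, geom)
    prev_grid = occupancy_grid(previous_session, geom) if previous_session is not None else grid
    irt_mean = irt_sd = None
    imputed = False
    if include_irt:
        irt_mean, irt_sd, imputed = irt_features(session)
    return FeatureVector(
        entries=head_entry_counts(session),
        traveled_distance=traveled_distance(session),
        speed_sd=speed_sd(session, speed_variant),
        location_entropy=location_entropy(grid),
        divergence=divergence(grid, prev_grid, smoothing),
        irt_mean=irt_mean,
        irt_sd=irt_sd,
        irt_imputed=imputed,
    )


def feature_table(
    sessions: list[TrajectorySession],
    geom: ChamberGeometry,
    smoothing: float = DT,
    include_irt: bool = False,
    speed_variant: str = "padded",
) -> pd.DataFrame:
    """One row per (subject, phase, session) with metadata and feature columns.

    Sessions are ordered per subject by (phase, session_index), schedule phase
    first; each session's divergence predecessor is the immediately preceding
    raw session of the same subject, across the phase boundary.
    """
    phase_order = {"SCHEDULE": 0, "EXTINCTION": 1}
    rows = []
    by_subject: dict[str, list[TrajectorySession]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, []).append(s)
    for subject_id in by_subject:
        ordered = sorted(
            by_subject[subject_id],
            key=lambda s: (phase_order[s.phase.value], s.session_index),
        )
        prev = None
        for s in ordered:
            fv = session_features(
                s, prev, geom,
                smoothing=smoothing, include_irt=include_irt,
                speed_variant=speed_variant,
            )
            row = {
                "subject": s.subject_id,
                "phase": s.phase.value,
                "session": s.session_index,
                "time_type": s.schedule.time_type.value,
                "space_type": s.schedule.space_type.value,
            }
            row.update(fv.as_dict(include_irt=include_irt))
            if include_irt:
                row["irt_imputed"] = fv.irt_imputed
            rows.append(row)
            prev = s
    return pd.DataFrame(rows)
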