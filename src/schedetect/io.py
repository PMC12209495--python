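"""Plain-CSV file contracts for sessions, events, manifests and features.

Each session is written as two files: a trajectory CSV (``t,x,y``) and an
event CSV (``t,event,dispenser`` with event in {entry, delivery, tone}).
A manifest CSV indexes every session of an experiment.  All files are
RFC-4180 CSV with a header row, "." decimal separator, and a leading
``# schedetect schema v1`` comment line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schedules import ChamberGeometry, Phase, ScheduleSpec, SpaceType, TimeType
from .simulate import DT, TrajectorySession

__all__ = [
    "write_session",
    "read_session",
    "write_experiment",
    "read_experiment",
    "write_features",
    "read_features",
    "validate_io",
    "Violation",
]

SCHEMA_COMMENT = "# schedetect schema v1"


def _session_stem(s: TrajectorySession) -> str:
    return f"{s.subject_id}_{s.phase.value.lower()}_{s.session_index:03d}"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    # keep_default_na off so the space-type token "NA" survives parsing
    return pd.read_csv(path, comment="#", keep_default_na=False, na_values=[""])


def write_session(session: TrajectorySession, out_dir: Path) -> tuple[Path, Path]:
    """Write one session's trajectory and event files; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = _session_stem(session)
    traj_path = out_dir / f"{stem}_traj.csv"
    ev_path = out_dir / f"{stem}_events.csv"
    traj = pd.DataFrame(session.samples, columns=["t", "x", "y"])
    _write_csv(traj, traj_path)

    events = []
    for t, d in session.head_entries:
        events.append((float(t), "entry", int(d)))
    for t, d in session.deliveries:
        events.append((float(t), "delivery", int(d)))
        events.append((float(t) - session.schedule.tone_lead, "tone", int(d)))
    events.sort(key=lambda e: e[0])
    _write_csv(pd.DataFrame(events, columns=["t", "event", "dispenser"]), ev_path)
    return traj_path, ev_path


def read_session(
    traj_path: Path, ev_path: Path, meta: dict
) -> TrajectorySession:
    """Rebuild a TrajectorySession from its two files plus manifest metadata."""
    traj = _read_csv(Path(traj_path))
    events = _read_csv(Path(ev_path))
    entries = events[events["event"] == "entry"]
    deliveries = events[events["event"] == "delivery"]
    spec = ScheduleSpec(
        time_type=TimeType(meta["time_type"]),
        space_type=SpaceType(meta["space_type"]),
        fixed_dispenser=int(meta.get("fixed_dispenser", 0)),
    )
    return TrajectorySession(
        subject_id=str(meta["subject"]),
        phase=Phase(meta["phase"]),
        session_index=int(meta["session"]),
        schedule=spec,
        samples=traj[["t", "x", "y"]].to_numpy(dtype=float),
        head_entries=entries[["t", "dispenser"]].to_numpy(dtype=float)
        if len(entries)
        else np.empty((0, 2)),
        deliveries=deliveries[["t", "dispenser"]].to_numpy(dtype=float)
        if len(deliveries)
        else np.empty((0, 2)),
    )


def write_experiment(sessions: list[TrajectorySession], out_dir: Path) -> Path:
    """Write all session files plus the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        traj_path, ev_path = write_session(s, out_dir)
        rows.append(
            {
                "subject": s.subject_id,
                "phase": s.phase.value,
                "session": s.session_index,
                "time_type": s.schedule.time_type.value,
                "space_type": s.schedule.space_type.value,
                "fixed_dispenser": s.schedule.fixed_dispenser,
                "traj_file": traj_path.name,
                "event_file": ev_path.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    _write_csv(pd.DataFrame(rows), manifest)
    return manifest


def read_experiment(directory: Path) -> list[TrajectorySession]:
    """Load every session listed in a directory's manifest."""
    directory = Path(directory)
    manifest = _read_csv(directory / "manifest.csv")
    sessions = []
    for _, row in manifest.iterrows():
        sessions.append(
            read_session(
                directory / row["traj_file"], directory / row["event_file"], row.to_dict()
            )
        )
    return sessions


def write_features(features: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_csv(features, path)
    return path


def read_features(path: Path) -> pd.DataFrame:
    return _read_csv(Path(path))


@dataclass(frozen=True)
class Violation:
    path: str
    message: str


def validate_io(directory: Path, expected_samples: int = 6000) -> list[Violation]:
    """Check an experiment directory: manifest present and complete, files
    present with the expected schemas and sample counts.

    Returns a (possibly empty) list of violations rather than raising, so a
    CLI wrapper can report all problems at once.
    """
    directory = Path(directory)
    violations: list[Violation] = []
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        return [Violation(str(manifest_path), "manifest.csv missing")]
    manifest = _read_csv(manifest_path)
    required = {"subject", "phase", "session", "time_type", "space_type", "traj_file", "event_file"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        return [Violation(str(manifest_path), f"manifest missing columns {sorted(missing_cols)}")]
    for _, row in manifest.iterrows():
        traj_path = directory / row["traj_file"]
        if not traj_path.exists():
            violations.append(Violation(str(traj_path), "trajectory file missing"))
            continue
        traj = _read_csv(traj_path)
        if list(traj.columns) != ["t", "x", "y"]:
            violations.append(Violation(str(traj_path), f"bad header {list(traj.columns)}"))
        elif len(traj) != expected_samples:
            violations.append(
                Violation(str(traj_path), f"expected {expected_samples} samples, found {len(traj)}")
            )
        ev_path = directory / row["event_file"]
        if not ev_path.exists():
            violations.append(Violation(str(ev_path), "event file missing"))
        else:
            ev = _read_csv(ev_path)
            if list(ev.columns) != ["t", "event", "dispenser"]:
                violations.append(Violation(str(ev_path), f"bad header {list(ev.columns)}"))
    # phase completeness per subject
    for subject, g in manifest.groupby("subject"):
        for phase in ("SCHEDULE", "EXTINCTION"):
            if not (g["phase"] == phase).any():
                violations.append(
                    Violation(str(manifest_path), f"subject {subject} has no {phase} sessions")
                )
    return violations
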