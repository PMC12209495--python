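"""End-to-end orchestration: simulate -> featurize -> detect -> stats.

``run_all`` executes the whole experiment from a single :class:`RunConfig`
and returns a :class:`RunReport` whose tables mirror the published analysis:
per-fold signal-detection metrics for the schedule task, 2AFC d' for the
component tasks, one exact Wilcoxon signed-rank test per (task, algorithm)
model with a Bonferroni-corrected threshold, and one Friedman test per task
comparing the four algorithms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .detect import ALGORITHMS, TASKS, FoldResult, results_frame, run_experiment
from .features import feature_table
from .schedules import ChamberGeometry, default_design
from .sdt import (
    ConfusionCounts,
    bonferroni_threshold,
    dprime_2afc,
    friedman,
    sdt_metrics,
    wilcoxon_one_sample,
)
from .simulate import simulate_experiment

__all__ = ["RunConfig", "RunReport", "run_all", "fold_metrics", "model_tests"]

log = logging.getLogger(__name__)

FAMILY_ALPHA = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a run; serialized config + code version
    fully determine all outputs."""

    seed: int = 0
    n_schedule_sessions: int = 30
    n_extinction_sessions: int = 10
    algorithms: tuple[str, ...] = ALGORITHMS
    tasks: tuple[str, ...] = TASKS
    smoothing: float = 0.2
    include_irt: bool = False
    speed_variant: str = "padded"
    standardize_mode: str = "fold"
    oversample_first: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown task(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("algorithms", "tasks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class RunReport:
    """All result tables of one run plus the decision log in force."""

    metrics: pd.DataFrame  # one row per (task, algorithm, subject)
    tests: pd.DataFrame  # one row per (task, algorithm): W, p, significance
    comparisons: pd.DataFrame  # one row per task: Friedman chi2, p
    predictions: pd.DataFrame  # one row per test-session prediction
    config: RunConfig

    def decision_log(self) -> dict:
        return {
            "standardize_mode": self.config.standardize_mode,
            "oversample_first": self.config.oversample_first,
            "speed_variant": self.config.speed_variant,
            "divergence_smoothing_s": self.config.smoothing,
            "speed_sd_divisor": "n (population)",
            "extreme_proportion_rule": "1/(2n)",
        }


def fold_metrics(results: list[FoldResult]) -> pd.DataFrame:
    """Per-fold outcome metrics.

    Schedule task: confusion counts -> sensitivity, specificity, d', c.
    Component tasks (single-class test sets): accuracy -> 2AFC d' only.
    """
    rows = []
    for r in results:
        row = {"task": r.label_kind, "algorithm": r.algorithm, "subject": r.test_subject}
        if r.label_kind == "schedule_vs_none":
            tp, fn, tn, fp = r.confusion()
            m = sdt_metrics(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
            row.update(
                d_prime=m.d_prime, criterion=m.criterion,
                sensitivity=m.sensitivity, specificity=m.specificity,
                accuracy=r.accuracy,
            )
        else:
            row.update(
                d_prime=dprime_2afc(r.accuracy, len(r.truth)),
                criterion=np.nan, sensitivity=np.nan, specificity=np.nan,
                accuracy=r.accuracy,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def model_tests(metrics: pd.DataFrame, alpha: float = FAMILY_ALPHA) -> pd.DataFrame:
    """One-sample exact Wilcoxon (d' > 0?) per (task, algorithm) model, with
    the Bonferroni threshold over the whole model family."""
    groups = list(metrics.groupby(["task", "algorithm"], sort=False))
    thr = bonferroni_threshold(alpha, len(groups))
    rows = []
    for (task, algorithm), g in groups:
        res = wilcoxon_one_sample(g["d_prime"].to_numpy(), mu0=0.0, alpha_corrected=thr)
        rows.append(
            {
                "task": task,
                "algorithm": algorithm,
                "W": res.statistic,
                "p": res.p_value,
                "n": res.n,
                "alpha_corrected": thr,
                "significant": res.p_value <= thr,
            }
        )
    return pd.DataFrame(rows)


def task_comparisons(metrics: pd.DataFrame) -> pd.DataFrame:
    """Friedman test per task: subjects as blocks, algorithms as treatments."""
    rows = []
    for task, g in metrics.groupby("task", sort=False):
        wide = g.pivot(index="subject", columns="algorithm", values="d_prime")
        if wide.shape[1] < 2:  # nothing to compare with one algorithm
            rows.append(
                {"task": task, "chi2": np.nan, "df": 0, "p": np.nan, "n_blocks": len(wide)}
            )
            continue
        res = friedman(wide.to_numpy())
        rows.append(
            {
                "task": task,
                "chi2": res.statistic,
                "df": wide.shape[1] - 1,
                "p": res.p_value,
                "n_blocks": res.n,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> RunReport:
    """Execute all stages in order; write artifacts if out_dir is set."""
    log.info("simulate: seed=%d, %d+%d sessions per subject", config.seed,
             config.n_schedule_sessions, config.n_extinction_sessions)
    geom = ChamberGeometry()
    sessions = simulate_experiment(
        default_design(),
        n_schedule_sessions=config.n_schedule_sessions,
        n_extinction_sessions=config.n_extinction_sessions,
        seed=config.seed,
        geom=geom,
    )
    log.info("featurize: %d sessions", len(sessions))
    features = feature_table(
        sessions, geom,
        smoothing=config.smoothing,
        include_irt=config.include_irt,
        speed_variant=config.speed_variant,
    )
    log.info("detect: algorithms=%s tasks=%s", config.algorithms, config.tasks)
    results = run_experiment(
        features,
        algorithms=config.algorithms,
        label_kinds=config.tasks,
        master_seed=config.seed,
        standardize_mode=config.standardize_mode,
        oversample_first=config.oversample_first,
        include_irt=config.include_irt,
    )
    metrics = fold_metrics(results)
    tests = model_tests(metrics)
    comparisons = task_comparisons(metrics)
    report = RunReport(
        metrics=metrics,
        tests=tests,
        comparisons=comparisons,
        predictions=results_frame(results),
        config=config,
    )
    if config.out_dir is not None:
        _write_report(report, sessions, features, Path(config.out_dir))
    return report


def _write_report(report: RunReport, sessions, features, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    sio.write_experiment(sessions, out_dir / "sessions")
    sio.write_features(features, out_dir / "features.csv")
    sio.write_features(report.predictions, out_dir / "predictions.csv")
    sio.write_features(report.metrics, out_dir / "metrics.csv")
    with open(out_dir / "tests.json", "w") as fh:
        json.dump(report.tests.to_dict(orient="records"), fh, indent=2)
    with open(out_dir / "comparisons.json", "w") as fh:
        json.dump(report.comparisons.to_dict(orient="records"), fh, indent=2)
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(report.config),
                "decisions": report.decision_log(),
            },
            fh,
            indent=2,
        )
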