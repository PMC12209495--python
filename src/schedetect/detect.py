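"""Leave-one-subject-out classification of schedule components.

Three binary tasks are defined over the per-session feature table:

* ``schedule_vs_none`` — schedule-phase sessions (positive) against
  extinction sessions (negative);
* ``fixed_vs_variable_space`` — fixed-space (positive) vs variable-space
  subjects, schedule phase only;
* ``ft_vs_vt`` — fixed-time (positive) vs variable-time subjects, schedule
  phase only.

The first five sessions of each phase are excluded for stability.  Each of
four classifiers (L2 logistic regression, RBF support-vector classifier,
100-tree random forest with entropy splits, and a dense 8-5-3-1 neural
network) is trained on 11 subjects and tested on the held-out subject,
cycling over all 12.  Training sets are balanced by random minority
oversampling and z-scored with training-set statistics before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import FEATURE_COLUMNS, IRT_COLUMNS

__all__ = [
    "TASKS",
    "ALGORITHMS",
    "SESSIONS_EXCLUDED_PER_PHASE",
    "ClassifierConfig",
    "LabeledDataset",
    "FoldResult",
    "build_dataset",
    "loso_folds",
    "oversample",
    "standardize",
    "train_classifier",
    "evaluate_fold",
    "run_experiment",
]

TASKS = ("schedule_vs_none", "fixed_vs_variable_space", "ft_vs_vt")
ALGORITHMS = ("LR", "SVC", "RF", "ANN")

#: First sessions of each phase dropped before analysis.
SESSIONS_EXCLUDED_PER_PHASE = 5


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters for one classifier kind.

    Stated choices: RF grows 100 trees on entropy splits; the ANN has hidden
    layers (5, 3) with ReLU, a sigmoid output trained on binary cross-entropy,
    and stops early once the loss has improved by less than 0.001 for 10
    consecutive epochs.  Remaining knobs (regularization strength 1.0, RBF
    width by the variance heuristic, sqrt-p feature subsampling, mini-batch
    adam capped at 1,000 epochs) are fixed defaults — no tuning.
    """

    kind: str
    seed: int = 0
    c_reg: float = 1.0
    n_trees: int = 100
    hidden_sizes: tuple[int, int] = (5, 3)
    early_stop_delta: float = 1e-3
    patience: int = 10
    max_epochs: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in ALGORITHMS:
            raise ValueError(f"unknown algorithm kind: {self.kind}")


@dataclass(frozen=True)
class LabeledDataset:
    """Feature rows with binary labels for one task."""

    frame: pd.DataFrame  # metadata + feature columns + "label"
    label_kind: str
    feature_columns: tuple[str, ...]

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject"].unique(), key=lambda s: (len(s), s))


@dataclass(frozen=True)
class FoldResult:
    test_subject: str
    label_kind: str
    algorithm: str
    truth: np.ndarray
    predictions: np.ndarray
    session_ids: list[tuple[str, int]]  # (phase, session) per test row

    @property
    def accuracy(self) -> float:
        return float((self.truth == self.predictions).mean())

    def confusion(self) -> tuple[int, int, int, int]:
        """(tp, fn, tn, fp); meaningful when both classes occur in truth."""
        t, p = self.truth, self.predictions
        tp = int(((t == 1) & (p == 1)).sum())
        fn = int(((t == 1) & (p == 0)).sum())
        tn = int(((t == 0) & (p == 0)).sum())
        fp = int(((t == 0) & (p == 1)).sum())
        return tp, fn, tn, fp


def _check_complete(features: pd.DataFrame) -> None:
    missing = []
    for subject, g in features.groupby("subject"):
        sched = set(g.loc[g["phase"] == "SCHEDULE", "session"])
        ext = set(g.loc[g["phase"] == "EXTINCTION", "session"])
        if sched and ext:
            continue
        missing.append((subject, "SCHEDULE" if not sched else "EXTINCTION"))
    if missing:
        raise ValueError(f"subjects missing a phase entirely: {missing}")


def build_dataset(
    features: pd.DataFrame, label_kind: str, include_irt: bool = False
) -> LabeledDataset:
    """Apply the session-exclusion rules and attach binary labels.

    Excludes the first five sessions of every phase.  For the two
    component tasks the extinction phase is dropped entirely (it carries no
    schedule to differentiate) and the label comes from the subject's
    schedule metadata.
    """
    if label_kind not in TASKS:
        raise ValueError(f"unknown label kind: {label_kind}")
    _check_complete(features)
    f = features[features["session"] > SESSIONS_EXCLUDED_PER_PHASE].copy()
    if label_kind == "schedule_vs_none":
        f["label"] = (f["phase"] == "SCHEDULE").astype(int)
    else:
        f = f[f["phase"] == "SCHEDULE"].copy()
        if label_kind == "fixed_vs_variable_space":
            f["label"] = (f["space_type"] == "FIXED").astype(int)
        else:
            f["label"] = (f["time_type"] == "FT").astype(int)
    cols = FEATURE_COLUMNS + (IRT_COLUMNS if include_irt else ())
    absent = [c for c in cols if c not in f.columns]
    if absent:
        raise ValueError(f"feature table lacks columns: {absent}")
    return LabeledDataset(
        frame=f.reset_index(drop=True), label_kind=label_kind, feature_columns=cols
    )


def loso_folds(dataset: LabeledDataset) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """One (train, test) split per subject; the test set is that subject's
    rows and the training set is everyone else's."""
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for s in subjects:
        test = dataset.frame[dataset.frame["subject"] == s]
        train = dataset.frame[dataset.frame["subject"] != s]
        folds.append((train, test))
    return folds


def oversample(train: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Balance classes by duplicating minority rows with replacement.

    All original rows are retained; extra minority rows are drawn uniformly
    with replacement until class counts match.
    """
    counts = train["label"].value_counts()
    if len(counts) < 2:
        raise ValueError("single-class training set: cannot oversample")
    if counts.iloc[0] == counts.iloc[-1]:
        return train
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    pool = train[train["label"] == minority]
    rng = np.random.default_rng(seed)
    extra = pool.iloc[rng.integers(0, len(pool), size=deficit)]
    return pd.concat([train, extra], ignore_index=True)


def standardize(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_columns: tuple[str, ...],
    mode: str = "fold",
) -> tuple[np.ndarray, np.ndarray]:
    """z-score features; constant columns map to 0.

    ``mode="fold"`` estimates mean/SD on the (oversampled) training rows and
    applies them to both sets (no leakage); ``mode="global"`` pools train and
    test rows for the estimate, mirroring a whole-dataset z-scoring.
    """
    xtr = train[list(feature_columns)].to_numpy(dtype=float)
    xte = test[list(feature_columns)].to_numpy(dtype=float)
    if mode == "fold":
        ref = xtr
    elif mode == "global":
        ref = np.vstack([xtr, xte])
    else:
        raise ValueError(f"unknown standardization mode: {mode}")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn("constant feature column(s) map to 0 after z-scoring")
        sd = np.where(constant, 1.0, sd)
    return (xtr - mean) / sd, (xte - mean) / sd


class _DenseNet:
    """Dense ReLU network with sigmoid output and loss-plateau early stop.

    Mini-batch adam (batch size min(200, n)): the loss-improvement early-stop
    rule (< delta for ``patience`` consecutive epochs) presumes several
    gradient updates per epoch; with one full-batch step per epoch the
    per-epoch improvement falls below delta while the loss is still high and
    training halts prematurely.
    """

    def __init__(self, config: ClassifierConfig, seed: int):
        self.config = config
        self.seed = seed
        self._net: MLPClassifier | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_DenseNet":
        c = self.config
        self._net = MLPClassifier(
            hidden_layer_sizes=c.hidden_sizes,
            activation="relu",
            solver="adam",
            alpha=0.0,
            batch_size="auto",
            max_iter=c.max_epochs,
            tol=c.early_stop_delta,
            n_iter_no_change=c.patience,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            self._net.fit(x, y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        assert self._net is not None, "fit before predict"
        # sigmoid output thresholded at 0.5
        return (self._net.predict_proba(x)[:, 1] >= 0.5).astype(int)


def train_classifier(config: ClassifierConfig, x: np.ndarray, y: np.ndarray):
    """Fit one classifier on standardized, balanced rows; returns an object
    with a ``predict(X) -> {0,1}`` contract."""
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    if config.kind == "LR":
        # liblinear with C and default penalty gives the L2-ridge objective
        model = LogisticRegression(
            C=config.c_reg, solver="liblinear",
            tol=1e-8, max_iter=10_000, random_state=config.seed,
        )
    elif config.kind == "SVC":
        model = SVC(C=config.c_reg, kernel="rbf", gamma="scale", random_state=config.seed)
    elif config.kind == "RF":
        model = RandomForestClassifier(
            n_estimators=config.n_trees, criterion="entropy",
            max_features="sqrt", random_state=config.seed,
        )
    else:  # ANN
        model = _DenseNet(config, seed=config.seed)
    return model.fit(x, y)


def evaluate_fold(
    model, test: pd.DataFrame, x_test: np.ndarray, algorithm: str, label_kind: str
) -> FoldResult:
    """Predict the held-out subject's sessions and record truth/predictions."""
    if len(test) == 0:
        raise ValueError("empty test set")
    preds = np.asarray(model.predict(x_test), dtype=int)
    return FoldResult(
        test_subject=str(test["subject"].iloc[0]),
        label_kind=label_kind,
        algorithm=algorithm,
        truth=test["label"].to_numpy(dtype=int),
        predictions=preds,
        session_ids=list(zip(test["phase"], test["session"].astype(int))),
    )


def _fold_seed(master_seed: int, task: str, algorithm: str, fold_idx: int) -> int:
    ss = np.random.SeedSequence(
        [master_seed, TASKS.index(task), ALGORITHMS.index(algorithm), fold_idx]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    features: pd.DataFrame,
    algorithms: tuple[str, ...] = ALGORITHMS,
    label_kinds: tuple[str, ...] = TASKS,
    master_seed: int = 0,
    standardize_mode: str = "fold",
    oversample_first: bool = True,
    include_irt: bool = False,
) -> list[FoldResult]:
    """Run the full cross-validated comparison.

    With all four algorithms and all three tasks over 12 subjects this yields
    144 fold evaluations.  Per-fold seeds are derived from the master seed, so
    repeated runs are bit-identical.  ``oversample_first`` controls whether
    standardization statistics are estimated after (default) or before
    balancing.
    """
    results: list[FoldResult] = []
    for task in label_kinds:
        dataset = build_dataset(features, task, include_irt=include_irt)
        folds = loso_folds(dataset)
        for algorithm in algorithms:
            for i, (train, test) in enumerate(folds):
                seed = _fold_seed(master_seed, task, algorithm, i)
                if oversample_first:
                    balanced = oversample(train, seed)
                    xtr, xte = standardize(balanced, test, dataset.feature_columns, standardize_mode)
                else:
                    xtr_plain, xte = standardize(train, test, dataset.feature_columns, standardize_mode)
                    balanced = oversample(
                        train.assign(**dict(zip(dataset.feature_columns, xtr_plain.T))), seed
                    )
                    xtr = balanced[list(dataset.feature_columns)].to_numpy(dtype=float)
                config = ClassifierConfig(kind=algorithm, seed=seed)
                model = train_classifier(config, xtr, balanced["label"].to_numpy(dtype=int))
                results.append(evaluate_fold(model, test, xte, algorithm, task))
    return results


def results_frame(results: list[FoldResult]) -> pd.DataFrame:
    """Flatten fold results to one row per test session prediction."""
    rows = []
    for r in results:
        for (phase, session), t, p in zip(r.session_ids, r.truth, r.predictions):
            rows.append(
                {
                    "task": r.label_kind,
                    "algorithm": r.algorithm,
                    "subject": r.test_subject,
                    "phase": phase,
                    "session": session,
                    "truth": int(t),
                    "prediction": int(p),
                }
            )
    return pd.DataFrame(rows)
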