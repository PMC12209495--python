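import numpy as np
import pandas as pd
import pytest

from schedetect import (
    ClassifierConfig,
    build_dataset,
    loso_folds,
    oversample,
    run_experiment,
    standardize,
    train_classifier,
)
from schedetect.detect import (
    ALGORITHMS,
    SESSIONS_EXCLUDED_PER_PHASE,
    evaluate_fold,
    results_frame,
)


def full_feature_frame(n_sched=30, n_ext=10) -> pd.DataFrame:
    """A hand-built feature table covering 12 subjects x (30 + 10) sessions
    with separable per-condition feature shifts (no simulation)."""
    rng = np.random.default_rng(99)
    rows = []
    for i in range(1, 13):
        space = "FIXED" if i <= 6 else "VARIABLE"
        time = "FT" if i in (1, 2, 3, 7, 8, 9) else "VT"
        for phase, count, ent_shift in (("SCHEDULE", n_sched, 0.0), ("EXTINCTION", n_ext, 2.0)):
            for k in range(1, count + 1):
                rows.append(
                    {
                        "subject": f"S{i}",
                        "phase": phase,
                        "session": k,
                        "time_type": time if phase == "SCHEDULE" else "NONE",
                        "space_type": space if phase == "SCHEDULE" else "NA",
                        "entries_d0": rng.poisson(50 if phase == "SCHEDULE" else 2),
                        "entries_d1": rng.poisson(10),
                        "entries_d2": rng.poisson(10),
                        "entries_d3": rng.poisson(10),
                        "traveled_distance": rng.normal(15000, 500),
                        "speed_sd": rng.normal(10, 1),
                        "location_entropy": rng.normal(
                            (2.0 if space == "FIXED" else 3.2) + ent_shift, 0.2
                        ),
                        "divergence": abs(rng.normal(0.3, 0.1)),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def features():
    return full_feature_frame()


class TestBuildDataset:
    def test_schedule_task_has_360_rows_300_positive(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        assert len(ds.frame) == 360
        assert int(ds.frame["label"].sum()) == 300
        per_subject = ds.frame.groupby("subject")["label"].agg(["size", "sum"])
        assert (per_subject["size"] == 30).all()
        assert (per_subject["sum"] == 25).all()

    def test_space_task_drops_extinction_and_balances_150_150(self, features):
        ds = build_dataset(features, "fixed_vs_variable_space")
        assert len(ds.frame) == 300
        assert int(ds.frame["label"].sum()) == 150
        assert (ds.frame["phase"] == "SCHEDULE").all()

    def test_time_task_is_150_150(self, features):
        ds = build_dataset(features, "ft_vs_vt")
        assert int(ds.frame["label"].sum()) == 150
        assert len(ds.frame) == 300

    def test_first_five_sessions_of_each_phase_excluded(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        assert ds.frame["session"].min() == SESSIONS_EXCLUDED_PER_PHASE + 1

    def test_subject_missing_a_phase_rejected(self, features):
        broken = features[
            ~((features["subject"] == "S3") & (features["phase"] == "SCHEDULE"))
        ]
        with pytest.raises(ValueError, match="S3"):
            build_dataset(broken, "schedule_vs_none")

    def test_unknown_label_kind_rejected(self, features):
        with pytest.raises(ValueError):
            build_dataset(features, "nonsense")


class TestLosoFolds:
    def test_twelve_subjects_give_twelve_disjoint_folds(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        folds = loso_folds(ds)
        assert len(folds) == 12
        seen = []
        for train, test in folds:
            test_subjects = set(test["subject"])
            assert len(test_subjects) == 1
            assert test_subjects.isdisjoint(set(train["subject"]))
            seen.append(test_subjects.pop())
        assert sorted(seen) == sorted(ds.subjects)

    def test_every_row_in_exactly_one_test_set(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        folds = loso_folds(ds)
        total = sum(len(test) for _, test in folds)
        assert total == len(ds.frame)

    def test_two_subject_toy_dataset(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        pair = ds.frame[ds.frame["subject"].isin(["S1", "S2"])]
        from schedetect.detect import LabeledDataset

        small = LabeledDataset(frame=pair, label_kind=ds.label_kind, feature_columns=ds.feature_columns)
        folds = loso_folds(small)
        assert len(folds) == 2
        assert set(folds[0][0]["subject"]) == {"S2"} or set(folds[0][0]["subject"]) == {"S1"}


class TestOversample:
    def test_275_55_becomes_balanced_with_originals_retained(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        train = ds.frame[ds.frame["subject"] != "S1"]
        assert train["label"].value_counts().to_dict() == {1: 275, 0: 55}
        balanced = oversample(train, seed=0)
        assert balanced["label"].value_counts().to_dict() == {1: 275, 0: 275}
        # all original rows retained, in order, ahead of the duplicates
        assert len(balanced) == 550
        pd.testing.assert_frame_equal(
            balanced.iloc[: len(train)].reset_index(drop=True), train.reset_index(drop=True)
        )

    def test_already_balanced_left_unchanged(self, features):
        ds = build_dataset(features, "ft_vs_vt")
        train = ds.frame[ds.frame["subject"] != "S1"]  # 125 vs 150? -> not balanced
        balanced_frame = ds.frame  # 150/150 overall
        assert oversample(balanced_frame, seed=0) is balanced_frame

    def test_same_seed_identical_resample(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        train = ds.frame[ds.frame["subject"] != "S1"]
        a = oversample(train, seed=5)
        b = oversample(train, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        pos_only = ds.frame[ds.frame["label"] == 1]
        with pytest.raises(ValueError, match="single-class"):
            oversample(pos_only, seed=0)


class TestStandardize:
    def test_training_columns_zscored(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        train = ds.frame[ds.frame["subject"] != "S1"]
        test = ds.frame[ds.frame["subject"] == "S1"]
        xtr, xte = standardize(train, test, ds.feature_columns)
        assert np.allclose(xtr.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(xtr.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_maps_to_zero_with_warning(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        train = ds.frame[ds.frame["subject"] != "S1"].copy()
        test = ds.frame[ds.frame["subject"] == "S1"].copy()
        train["divergence"] = 1.0
        test["divergence"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            xtr, xte = standardize(train, test, ds.feature_columns)
        j = ds.feature_columns.index("divergence")
        assert np.all(xtr[:, j] == 0.0) and np.all(xte[:, j] == 0.0)

    def test_fold_statistics_differ_from_test_own_statistics(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        train = ds.frame[ds.frame["subject"] != "S1"]
        test = ds.frame[ds.frame["subject"] == "S1"].copy()
        test["traveled_distance"] += 10_000  # shifted test subject
        _, with_train_stats = standardize(train, test, ds.feature_columns, mode="fold")
        _, with_own_stats = standardize(test, test, ds.feature_columns, mode="fold")
        j = ds.feature_columns.index("traveled_distance")
        assert not np.allclose(with_train_stats[:, j], with_own_stats[:, j])


def separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal([-3, -3], 0.3, size=(n // 2, 2))
    x1 = rng.normal([3, 3], 0.3, size=(n // 2, 2))
    x = np.vstack([x0, x1])
    y = np.repeat([0, 1], n // 2)
    return x, y


class TestClassifiers:
    @pytest.mark.parametrize("kind", ALGORITHMS)
    def test_all_four_fit_a_separable_toy_set_perfectly(self, kind):
        x, y = separable_toy()
        model = train_classifier(ClassifierConfig(kind=kind, seed=0), x, y)
        assert (model.predict(x) == y).mean() == 1.0

    def test_logreg_matches_brute_force_objective_minimizer(self):
        # 1-D logistic regression with L2; grid-search the regularized
        # negative log-likelihood over (w, b) and compare decision boundary
        x, y = separable_toy(n=30, seed=1)
        x = x[:, :1]
        model = train_classifier(ClassifierConfig(kind="LR", seed=0), x, y)

        def objective(w, b):
            z = w * x[:, 0] + b
            ll = np.sum(np.log1p(np.exp(-z)) * y + np.log1p(np.exp(z)) * (1 - y))
            return ll + 0.5 * w**2  # C = 1 -> 0.5 * ||w||^2 (bias unpenalized)

        ws = np.linspace(-5, 5, 201)
        bs = np.linspace(-5, 5, 201)
        grid = np.array([[objective(w, b) for b in bs] for w in ws])
        iw, ib = np.unravel_index(np.argmin(grid), grid.shape)
        w_star, b_star = ws[iw], bs[ib]
        preds_oracle = (w_star * x[:, 0] + b_star > 0).astype(int)
        assert np.array_equal(model.predict(x), preds_oracle)

    def test_ann_identical_seed_identical_predictions(self):
        x, y = separable_toy(seed=2)
        a = train_classifier(ClassifierConfig(kind="ANN", seed=7), x, y).predict(x)
        b = train_classifier(ClassifierConfig(kind="ANN", seed=7), x, y).predict(x)
        assert np.array_equal(a, b)

    def test_nonfinite_features_rejected(self):
        x, y = separable_toy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_classifier(ClassifierConfig(kind="LR", seed=0), x, y)


class TestEvaluateAndRun:
    def test_confusion_counts_for_perfect_predictions(self, features):
        ds = build_dataset(features, "schedule_vs_none")
        test = ds.frame[ds.frame["subject"] == "S1"]

        class Oracle:
            def predict(self, x):
                return test["label"].to_numpy()

        r = evaluate_fold(Oracle(), test, np.zeros((len(test), 1)), "LR", "schedule_vs_none")
        assert r.confusion() == (25, 0, 5, 0)

    def test_single_class_test_set_uses_accuracy(self, features):
        ds = build_dataset(features, "ft_vs_vt")
        test = ds.frame[ds.frame["subject"] == "S1"]

        class AlwaysPositive:
            def predict(self, x):
                return np.ones(len(x), dtype=int)

        r = evaluate_fold(AlwaysPositive(), test, np.zeros((len(test), 1)), "LR", "ft_vs_vt")
        assert r.accuracy == 1.0
        assert set(r.truth) == {1}

    def test_empty_test_set_rejected(self, features):
        ds = build_dataset(features, "ft_vs_vt")
        empty = ds.frame.iloc[0:0]
        with pytest.raises(ValueError):
            evaluate_fold(None, empty, np.zeros((0, 1)), "LR", "ft_vs_vt")

    def test_full_run_produces_144_fold_results(self, features):
        results = run_experiment(features, master_seed=3)
        assert len(results) == 144
        frame = results_frame(results)
        assert set(frame["algorithm"]) == set(ALGORITHMS)

    def test_single_algorithm_single_task_gives_12_folds(self, features):
        results = run_experiment(features, algorithms=("LR",), label_kinds=("ft_vs_vt",), master_seed=0)
        assert len(results) == 12

    def test_no_leakage_test_subject_absent_from_training(self, features):
        # the structural guarantee: folds are built by subject partition
        ds = build_dataset(features, "schedule_vs_none")
        for train, test in loso_folds(ds):
            assert set(test["subject"]).isdisjoint(set(train["subject"]))

    def test_repeated_run_same_master_seed_identical(self, features):
        a = results_frame(run_experiment(features, algorithms=("LR", "ANN"), master_seed=5))
        b = results_frame(run_experiment(features, algorithms=("LR", "ANN"), master_seed=5))
        pd.testing.assert_frame_equal(a, b)
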