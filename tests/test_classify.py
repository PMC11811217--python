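"""Point-biserial selection, confusion-matrix metrics, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from cardiocausal.classify import (
    ALGORITHMS,
    compute_metrics,
    crossval_classify,
    evaluate_feature_sets,
    point_biserial,
    select_correlated,
)


class TestPointBiserial:
    def test_worked_example(self):
        # Pearson on the 0/1 coding is the oracle:
        # values 1..6, labels 000111 -> (5-2)/sd_pop * sqrt(9/36) ~ 0.8783
        v = np.arange(1.0, 7.0)
        y = np.array([0, 0, 0, 1, 1, 1])
        r = point_biserial(v, y)
        oracle = np.corrcoef(v, y)[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)
        assert r == pytest.approx(0.8783, abs=1e-4)
        m1, m0 = v[y == 1].mean(), v[y == 0].mean()
        manual = (m1 - m0) / v.std() * np.sqrt(9 / 36)
        assert r == pytest.approx(manual, abs=1e-12)

    def test_equal_group_means_give_zero(self):
        v = np.array([1.0, 3.0, 2.0, 1.0, 3.0, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert point_biserial(v, y) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_label_flip(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        assert point_biserial(v, y) == pytest.approx(-point_biserial(v, 1 - y))

    def test_undefined_cases_are_nan(self):
        y = np.array([0, 1, 0, 1])
        assert np.isnan(point_biserial(np.ones(4), y))
        assert np.isnan(point_biserial(np.arange(4.0), np.zeros(4)))

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            point_biserial(np.arange(4.0), np.array([0, 1, 2, 1]))


class TestSelectCorrelated:
    def test_k_zero_empty_and_k_bounds(self, planted_frame):
        df, _ = planted_frame
        X, y = df.drop(columns=["label"]), df["label"]
        assert select_correlated(X, y, 0) == []
        with pytest.raises(ValueError, match="k"):
            select_correlated(X, y, 99)

    def test_confounded_feature_enters_correlation_list(self, planted_frame):
        df, dag = planted_frame
        X, y = df.drop(columns=["label"]), df["label"]
        k = len(dag.adjacent_to_label())  # equal-size comparison arms
        top = select_correlated(X, y, k)
        assert "f_spur" in top
        assert "f_spur" not in dag.adjacent_to_label()


class TestComputeMetrics:
    def test_perfect_confusion_matrix(self):
        m = compute_metrics(10, 0, 0, 10)
        assert (m["accuracy"], m["precision"], m["recall"], m["f1"]) == (1, 1, 1, 1)
        assert m["zero_denominator"] == []

    def test_closed_form_example(self):
        m = compute_metrics(8, 2, 3, 7)
        assert m["accuracy"] == pytest.approx(15 / 20)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(8 / 11)
        f1 = 2 * 0.8 * (8 / 11) / (0.8 + 8 / 11)
        assert m["f1"] == pytest.approx(f1, abs=1e-12)

    def test_zero_denominator_flagged(self):
        m = compute_metrics(0, 0, 5, 5)
        assert m["precision"] == 0.0 and m["recall"] == 0.0
        assert "precision" in m["zero_denominator"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_metrics(1, -1, 0, 0)

    @given(
        tp=st.integers(0, 500),
        fp=st.integers(0, 500),
        fn=st.integers(0, 500),
        tn=st.integers(0, 500),
    )
    @settings(derandomize=True, max_examples=200)
    def test_metrics_bounded_and_f1_harmonic(self, tp, fp, fn, tn):
        assume(tp + fp + fn + tn > 0)
        m = compute_metrics(tp, fp, fn, tn)
        for key in ("accuracy", "precision", "recall", "f1"):
            assert 0.0 <= m[key] <= 1.0
        if m["precision"] + m["recall"] > 0:
            h = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
            assert m["f1"] == pytest.approx(h, abs=1e-12)


def _separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = pd.Series(np.repeat([0, 1], n // 2))
    X = pd.DataFrame({"a": y + 0.01 * rng.normal(size=n), "b": rng.normal(size=n)})
    return X, y


class TestCrossval:
    def test_separable_features_score_one(self):
        X, y = _separable()
        rep = crossval_classify(X, y, "logistic_regression", folds=5, seed=0)
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0
        assert rep.auc == 1.0

    def test_f1_consistent_with_precision_recall(self, planted_frame):
        df, _ = planted_frame
        rep = crossval_classify(
            df[["f_causal", "conf"]], df["label"], "naive_bayes", folds=10, seed=1
        )
        expected = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
        assert rep.f1 == pytest.approx(expected, abs=1e-9)
        assert 0 <= rep.auc <= 1

    def test_label_independent_features_sit_at_chance(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(400, 4)), columns=list("abcd"))
            y = pd.Series(np.repeat([0, 1], 200))
            rep = crossval_classify(X, y, "logistic_regression", folds=5, seed=seed)
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = pd.Series(np.repeat([0, 1], 100))
        base = y + rng.normal(size=200)
        r1 = crossval_classify(
            pd.DataFrame({"x": base}), y, "logistic_regression", folds=5, seed=0
        )
        r2 = crossval_classify(
            pd.DataFrame({"x": np.exp(base / 2)}), y, "naive_bayes", folds=5, seed=0
        )
        # AUC depends only on the ranking of scores, so a strictly monotone
        # re-expression of a single feature cannot change it much even
        # across model families
        assert r1.auc == pytest.approx(r2.auc, abs=0.03)

    def test_stratified_folds_balance_classes(self, planted_frame):
        df, _ = planted_frame
        rep = crossval_classify(
            df[["f_causal"]], df["label"], "decision_tree", folds=10, seed=0
        )
        y = df["label"].to_numpy()
        per_fold = [
            y[rep.fold_assignments == k].sum() for k in range(10)
        ]
        assert max(per_fold) - min(per_fold) <= 1

    def test_unknown_algorithm_lists_valid_names(self):
        X, y = _separable()
        with pytest.raises(ValueError, match="random_forest"):
            crossval_classify(X, y, "svm", folds=5)

    def test_too_small_class_rejected(self):
        X, y = _separable(n=10)
        with pytest.raises(ValueError, match="10-fold|subjects per class"):
            crossval_classify(X, y, "naive_bayes", folds=10)


class TestEvaluateFeatureSets:
    def test_report_covers_all_algorithms_and_arms(self, planted_frame):
        df, dag = planted_frame
        causal = sorted(dag.adjacent_to_label())
        table = evaluate_feature_sets(
            df.drop(columns=["label"]).join(df["label"]),
            df["label"],
            causal,
            folds=5,
            seed=0,
        )
        assert len(table) == 2 * len(ALGORITHMS)
        assert set(table["feature_set"]) == {"causal", "correlation"}
        assert set(table["algorithm"]) == set(ALGORITHMS)
        assert table[["accuracy", "precision", "recall", "f1", "auc"]].apply(
            lambda c: c.between(0, 1).all()
        ).all()
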