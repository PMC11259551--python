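import numpy as np
import pandas as pd
import pytest

from ventpack.modeling import (
    MODEL_FAMILIES,
    ModelSpec,
    build_model,
    cross_validate,
    evaluate,
    label_decline,
    predict_scores,
    rusboost_train,
    split_cohort,
)


class TestLabelDecline:
    def test_rapid_above_threshold(self):
        # (2.50 - 2.10) / (31/12) = 0.1548 L/yr
        assert label_decline(2.50, 2.10, 31) == "rapid"

    def test_stable_at_zero_decline(self):
        assert label_decline(2.50, 2.50, 24) == "stable"

    def test_boundary_inclusive(self):
        # (2.50 - 2.38) / 2 = exactly 60 mL/yr -> rapid
        assert label_decline(2.50, 2.38, 24) == "rapid"

    def test_improvement_is_stable(self):
        assert label_decline(2.0, 2.4, 36) == "stable"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            label_decline(-1.0, 2.0, 24)
        with pytest.raises(ValueError):
            label_decline(2.0, 2.0, 0)


def cohort_frame(n_stable=57, n_rapid=31):
    return pd.DataFrame(
        {
            "id": [f"S{i}" for i in range(n_stable + n_rapid)],
            "label": ["stable"] * n_stable + ["rapid"] * n_rapid,
        }
    )


class TestSplitCohort:
    def test_stratified_sizes(self):
        df = cohort_frame()
        train, test = split_cohort(df, 0.2, seed=0)
        assert len(train) + len(test) == 88
        assert set(train.index).isdisjoint(test.index)
        assert abs(len(test) - 0.2 * 88) <= 1
        assert (test["label"] == "rapid").sum() in (6, 7)

    def test_zero_fraction_warns_empty_test(self):
        with pytest.warns(UserWarning, match="empty test"):
            train, test = split_cohort(cohort_frame(), 0.0, seed=0)
        assert len(test) == 0
        assert len(train) == 88

    def test_reproducible(self):
        df = cohort_frame()
        _, t1 = split_cohort(df, 0.2, seed=5)
        _, t2 = split_cohort(df, 0.2, seed=5)
        assert list(t1.index) == list(t2.index)


def separable_data(seed, n=88, margin=2.0):
    rng = np.random.default_rng(seed)
    y = np.array(["stable"] * (n - n // 3) + ["rapid"] * (n // 3))
    X = rng.standard_normal((n, 4))
    X[:, 0] += np.where(y == "rapid", margin, 0.0)
    X[:, 1] -= np.where(y == "rapid", margin, 0.0)
    return X, y


class TestCrossValidate:
    @pytest.mark.parametrize("family", ["logistic", "svm_rbf_medium"])
    def test_separable_high_auc(self, family):
        aucs = []
        for seed in range(5):
            X, y = separable_data(seed)
            spec = ModelSpec(family=family, seed=seed)
            aucs.append(cross_validate(spec, X, y, folds=5, seed=seed)["mean_cv_auc"])
        assert np.mean(aucs) >= 0.95

    def test_permuted_labels_chance_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = separable_data(seed)
            y = rng.permutation(y)
            spec = ModelSpec(family="logistic", seed=seed)
            aucs.append(cross_validate(spec, X, y, folds=5, seed=seed)["mean_cv_auc"])
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_folds_partition_training_set(self):
        X, y = separable_data(3)
        cv = cross_validate(ModelSpec(family="decision_tree", seed=3), X, y, folds=5, seed=3)
        assert not np.isnan(cv["oof_scores"]).any()  # every row validated once
        assert len(cv["fold_metrics"]) == 5


class TestRegistry:
    def test_all_families_train_and_score(self):
        X, y = separable_data(1)
        y01 = (y == "rapid").astype(int)
        for family in MODEL_FAMILIES:
            model = build_model(ModelSpec(family=family, seed=0), X.shape[1])
            model.fit(X, y01)
            s = predict_scores(model, X)
            assert s.shape == (len(y),)
            assert np.all((s >= 0) & (s <= 1))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            ModelSpec(family="perceptron")


class TestRUSBoost:
    def test_balanced_separable_training_accuracy(self):
        X, y = separable_data(0, n=80)
        model = rusboost_train(X, (y == "rapid").astype(int), rounds=30, seed=0)
        acc = (model.predict(X) == (y == "rapid").astype(int)).mean()
        assert acc >= 0.95

    def test_imbalanced_minority_sensitivity(self):
        """On 80/20 imbalanced well-separated data, the per-round
        undersampling keeps minority sensitivity high (and at least as
        high as a plain imbalanced-fit tree), averaged over seeds."""
        from sklearn.tree import DecisionTreeClassifier

        rus_sens, tree_sens = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 3))
            y = np.array([0] * 160 + [1] * 40)
            X[y == 1, 0] += 3.0
            tr = rng.permutation(200)[:150]
            te = np.setdiff1d(np.arange(200), tr)
            model = rusboost_train(X[tr], y[tr], rounds=40, seed=seed)
            rus_sens.append((model.predict(X[te])[y[te] == 1] == 1).mean())
            tree = DecisionTreeClassifier(max_depth=3, random_state=seed).fit(X[tr], y[tr])
            tree_sens.append((tree.predict(X[te])[y[te] == 1] == 1).mean())
        assert np.mean(rus_sens) >= 0.8
        assert np.mean(rus_sens) >= np.mean(tree_sens)

    def test_single_round_single_tree(self):
        X, y = separable_data(2, n=60)
        model = rusboost_train(X, (y == "rapid").astype(int), rounds=1, seed=2)
        assert len(model.estimators_) == 1

    def test_deterministic(self):
        X, y = separable_data(6, n=60)
        y01 = (y == "rapid").astype(int)
        a = rusboost_train(X, y01, rounds=20, seed=9).decision_function(X)
        b = rusboost_train(X, y01, rounds=20, seed=9).decision_function(X)
        assert np.array_equal(a, b)


class TestEvaluate:
    def test_confusion_matrix_arithmetic(self):
        scores = np.concatenate([
            np.full(25, 0.9), np.full(9, 0.1),   # positives: 25 TP, 9 FN
            np.full(4, 0.9), np.full(50, 0.1),   # negatives: 4 FP, 50 TN
        ])
        labels = np.array([True] * 34 + [False] * 54)
        m = evaluate(scores, labels)
        assert (m.tp, m.fp, m.tn, m.fn) == (25, 4, 50, 9)
        assert m.sensitivity == pytest.approx(25 / 34, abs=5e-4)
        assert m.specificity == pytest.approx(50 / 54, abs=5e-4)
        assert m.accuracy == pytest.approx(75 / 88, abs=5e-4)
        assert m.f1 == pytest.approx(2 * 25 / (2 * 25 + 4 + 9), abs=5e-4)

    def test_perfect_scores(self):
        m = evaluate(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0], dtype=bool))
        assert m.auc == 1.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_constant_scores_chance_auc(self):
        m = evaluate(np.full(10, 0.5), np.array([1, 0] * 5, dtype=bool))
        assert m.auc == pytest.approx(0.5)

    def test_identities_on_random_counts(self, rng):
        for _ in range(20):
            n_pos = int(rng.integers(1, 30))
            n_neg = int(rng.integers(1, 30))
            scores = rng.random(n_pos + n_neg)
            labels = np.array([True] * n_pos + [False] * n_neg)
            m = evaluate(scores, labels, threshold=float(rng.random()))
            assert m.tp + m.fn == n_pos
            assert m.tn + m.fp == n_neg
            assert m.accuracy == pytest.approx((m.tp + m.tn) / (n_pos + n_neg))
            denom = 2 * m.tp + m.fp + m.fn
            if denom:
                assert m.f1 == pytest.approx(2 * m.tp / denom)
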