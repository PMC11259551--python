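"""Rapid-decliner labeling, cohort splitting, classifiers and evaluation.

The binary outcome is *rapid decline*: an annualized FEV1 loss of at
least 60 mL/year between the two visits (boundary inclusive), each
subject annualized over their own follow-up interval.  Ten classifier
families are supported, mirroring common clinical-ML toolkits: logistic
regression, Gaussian naive Bayes, a medium-scale RBF SVM, a decision
tree, cosine-metric KNN, bagged and boosted trees, random-subspace LDA
and KNN ensembles, and RUSBoost (AdaBoost with per-round random
undersampling of the majority class), which is implemented here directly
because class imbalance is intrinsic to the problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .stats import auc_mann_whitney

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "EvalMetrics",
    "RUSBoostClassifier",
    "label_decline",
    "split_cohort",
    "build_model",
    "default_grid",
    "cross_validate",
    "rusboost_train",
    "evaluate",
    "predict_scores",
]

RAPID_THRESHOLD_L_PER_YEAR = 0.060

MODEL_FAMILIES = (
    "logistic",
    "naive_bayes",
    "svm_rbf_medium",
    "decision_tree",
    "knn_cosine",
    "bagged_trees",
    "boosted_trees",
    "subspace_lda",
    "subspace_knn",
    "rusboost",
)


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with hyperparameters and a seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {MODEL_FAMILIES}")


@dataclass(frozen=True)
class EvalMetrics:
    """Threshold metrics from the confusion matrix plus the AUC."""

    auc: float
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int


def label_decline(fev1_baseline: float, fev1_followup: float, interval_months: float) -> str:
    """Label a subject ``rapid`` iff annualized FEV1 decline >= 60 mL/year.

    Decline = (baseline - followup) / (interval_months / 12) in L/year;
    the 0.060 L/year boundary is inclusive.
    """
    if fev1_baseline <= 0 or fev1_followup <= 0 or interval_months <= 0:
        raise ValueError("FEV1 values and interval must be positive")
    decline = (fev1_baseline - fev1_followup) / (interval_months / 12.0)
    return "rapid" if decline >= RAPID_THRESHOLD_L_PER_YEAR else "stable"


def split_cohort(
    table: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    label_col: str = "label",
    stratify: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label-stratified, reproducible train/test split of the cohort."""
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must be in [0, 1)")
    if test_fraction == 0:
        warnings.warn("test_fraction 0: empty test set")
        return table.copy(), table.iloc[0:0].copy()
    rng = np.random.default_rng(seed)
    test_idx: list = []
    if stratify:
        for _, grp in table.groupby(label_col, sort=True):
            k = int(round(test_fraction * len(grp)))
            k = max(min(k, len(grp) - 1), 1 if len(grp) > 1 else 0)
            test_idx.extend(rng.choice(grp.index.to_numpy(), size=k, replace=False))
    else:
        k = int(round(test_fraction * len(table)))
        test_idx.extend(rng.choice(table.index.to_numpy(), size=k, replace=False))
    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask].copy(), table.loc[test_mask].copy()


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost with random undersampling of the majority class each round.

    Each boosting round draws a balanced sample: all minority-class rows
    plus a weighted random undersample of the majority class down to the
    minority count (sampling probabilities proportional to the current
    boosting weights).  A depth-limited tree is fit on the balanced
    sample, its weighted error computed on the *full* training set, and
    sample weights updated by the usual multiplicative AdaBoost rule.
    Scores are weighted vote margins mapped to [0, 1].
    """

    def __init__(self, n_rounds: int = 50, max_depth: int = 10, random_state: int = 0):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("RUSBoost is a binary classifier")
        yy = np.where(y == self.classes_[1], 1, -1)
        n = len(yy)
        rng = np.random.default_rng(self.random_state)
        w = np.full(n, 1.0 / n)

        counts = {c: int((y == c).sum()) for c in self.classes_}
        minority = min(counts, key=counts.get)
        min_idx = np.flatnonzero(y == minority)
        maj_idx = np.flatnonzero(y != minority)

        self.estimators_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        for _ in range(self.n_rounds):
            if len(maj_idx) > len(min_idx):
                p = w[maj_idx] / w[maj_idx].sum()
                take = rng.choice(maj_idx, size=len(min_idx), replace=False, p=p)
                sample = np.concatenate([min_idx, take])
            else:
                sample = np.arange(n)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, random_state=int(rng.integers(2**31 - 1))
            )
            tree.fit(X[sample], yy[sample])
            pred = tree.predict(X)
            err = float(w[pred != yy].sum())
            if err >= 0.5:
                continue  # worse than chance on the weighted sample: skip round
            err = max(err, 1e-10)
            alpha = 0.5 * np.log((1.0 - err) / err)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            w *= np.exp(-alpha * yy * pred)
            w /= w.sum()
            if err <= 1e-10:
                break
        if not self.estimators_:
            # degenerate data: fall back to a single balanced tree
            tree = DecisionTreeClassifier(max_depth=self.max_depth, random_state=self.random_state)
            tree.fit(X, yy)
            self.estimators_ = [tree]
            self.alphas_ = [1.0]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        total = np.zeros(len(X))
        for alpha, tree in zip(self.alphas_, self.estimators_):
            total += alpha * tree.predict(X)
        return total / sum(self.alphas_)

    def predict_proba(self, X):
        margin = self.decision_function(X)  # in [-1, 1]
        p1 = (margin + 1.0) / 2.0
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def rusboost_train(X, y, rounds: int = 50, seed: int = 0, max_depth: int = 10) -> RUSBoostClassifier:
    """Fit a RUSBoost ensemble; ``rounds = 1`` reduces to one undersampled tree."""
    return RUSBoostClassifier(n_rounds=rounds, max_depth=max_depth, random_state=seed).fit(X, y)


def build_model(spec: ModelSpec, n_features: int):
    """Instantiate the classifier for ``spec`` (standardization included
    where the family is scale-sensitive).

    The "medium" RBF SVM uses kernel scale sqrt(n_features), i.e.
    gamma = 1 / n_features on standardized inputs.
    """
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    fam = spec.family
    if fam == "logistic":
        est = LogisticRegression(C=hp.get("C", 1.0), max_iter=2000, random_state=seed)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if fam == "naive_bayes":
        return GaussianNB()
    if fam == "svm_rbf_medium":
        gamma = hp.get("gamma", 1.0 / max(n_features, 1))
        # scores come from the decision function through a logistic map
        est = SVC(kernel="rbf", C=hp.get("C", 1.0), gamma=gamma, random_state=seed)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if fam == "decision_tree":
        return DecisionTreeClassifier(max_depth=hp.get("max_depth", 4), random_state=seed)
    if fam == "knn_cosine":
        est = KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 10), metric="cosine")
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if fam == "bagged_trees":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=seed, n_jobs=1
        )
    if fam == "boosted_trees":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=hp.get("max_depth", 2)),
            n_estimators=hp.get("n_estimators", 50),
            random_state=seed,
        )
    if fam == "subspace_lda":
        est = BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=hp.get("n_estimators", 30),
            max_features=0.5,
            bootstrap=False,
            random_state=seed,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if fam == "subspace_knn":
        est = BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5)),
            n_estimators=hp.get("n_estimators", 30),
            max_features=0.5,
            bootstrap=False,
            random_state=seed,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if fam == "rusboost":
        return RUSBoostClassifier(
            n_rounds=hp.get("n_rounds", 50),
            max_depth=hp.get("max_depth", 10),
            random_state=seed,
        )
    raise ValueError(f"unknown family {fam!r}")


#: small hyperparameter grids searched inside the CV loop
_GRIDS: dict[str, list[dict]] = {
    "logistic": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "naive_bayes": [{}],
    "svm_rbf_medium": [{"C": c} for c in (0.5, 1.0, 4.0)],
    "decision_tree": [{"max_depth": d} for d in (3, 4, 6)],
    "knn_cosine": [{"n_neighbors": k} for k in (5, 10)],
    "bagged_trees": [{"n_estimators": 100}],
    "boosted_trees": [{"n_estimators": n} for n in (30, 50)],
    "subspace_lda": [{}],
    "subspace_knn": [{}],
    "rusboost": [{"n_rounds": r} for r in (30, 50)],
}


def default_grid(family: str) -> list[dict]:
    return [dict(g) for g in _GRIDS[family]]


def predict_scores(model, X) -> np.ndarray:
    """Positive-class score in [0, 1] for any registry model."""
    X = np.asarray(X, dtype=float)
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    from scipy.special import expit

    return expit(model.decision_function(X))


def cross_validate(
    spec: ModelSpec,
    X,
    y,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold CV: mean validation AUC and per-fold metrics.

    Folds partition the training set exactly (each row validated once).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics = []
    scores_all = np.full(len(y), np.nan)
    for tr, va in skf.split(X, y):
        model = build_model(spec, X.shape[1])
        model.fit(X[tr], (y[tr] == _positive_class(y)).astype(int))
        s = predict_scores(model, X[va])
        scores_all[va] = s
        fold_metrics.append(evaluate(s, y[va] == _positive_class(y)))
    mean_auc = float(np.mean([m.auc for m in fold_metrics]))
    return {"mean_cv_auc": mean_auc, "fold_metrics": fold_metrics, "oof_scores": scores_all}


def _positive_class(y: np.ndarray):
    classes = np.unique(y)
    if "rapid" in classes.tolist():
        return "rapid"
    return classes[-1]


def evaluate(scores, labels, threshold: float = 0.5) -> EvalMetrics:
    """Confusion-matrix metrics at ``threshold`` plus the midrank AUC.

    Satisfies the defining identities exactly:
    f1 = 2TP / (2TP + FP + FN), accuracy = (TP + TN) / total.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    tn = int((~pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec_ = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    acc = (tp + tn) / len(labels) if len(labels) else 0.0
    try:
        auc = auc_mann_whitney(scores, labels)
    except ValueError:
        auc = float("nan")
    return EvalMetrics(
        auc=auc, sensitivity=sens, specificity=spec_, f1=f1, accuracy=acc,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )
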