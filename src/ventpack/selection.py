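"""Feature standardization, PCA diagnostics and Boruta selection.

PCA here is diagnostic: it reports the variance structure of the feature
table but does not feed the classifiers.  The final feature subset comes
from Boruta, an all-relevant wrapper around a random forest: each
iteration appends permuted "shadow" copies of the features, fits the
forest, and scores a feature a *hit* when its importance exceeds the 95th
percentile of the shadow importances.  Hit counts are tested against a
Binomial(iterations, 1/2) null with a two-step multiplicity correction
(step-up FDR plus a Bonferroni bound), confirming or rejecting features
as evidence accumulates; whatever is undecided at the iteration cap stays
*tentative* and is excluded downstream.

Two implementation choices matter for calibration and are documented in
the methods note:

* importance is *holdout permutation importance* (the forest is fit on a
  70% split each iteration and a feature's importance is the drop in mean
  correct-class probability on the 30% holdout when that feature's column
  is permuted).  Unlike impurity importance, this does not systematically
  reward features whose association with the outcome is a fixed sampling
  accident, so the false-confirmation rate stays controlled.
* the shadow pool never shrinks below the original feature count: when
  features are rejected and dropped, extra independent permutations are
  added so the hit threshold keeps its original calibration.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["standardize", "PCAResult", "pca", "BorutaParams", "BorutaResult", "boruta_select"]

logger = logging.getLogger(__name__)


def standardize(X: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise z-scoring with the population (ddof = 0) SD convention.

    Returns (standardized table, means, SDs).  Zero-variance columns are
    mapped to 0 with a warning; their recorded SD is 0.
    """
    df = pd.DataFrame(X).copy()
    if len(df) < 2:
        raise ValueError("need at least two rows to standardize")
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=0)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance column(s) mapped to 0 during standardization"
        )
    safe = sds.replace(0.0, 1.0)
    Z = (df - means) / safe
    Z.loc[:, constant] = 0.0
    return Z, means, sds


@dataclass(frozen=True)
class PCAResult:
    """Eigenvalues (descending), loadings (columns = components) and
    explained-variance ratios of the column covariance matrix."""

    eigenvalues: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(X: pd.DataFrame | np.ndarray) -> PCAResult:
    """Eigen-decomposition of the (population) covariance matrix of ``X``.

    On standardized input this equals the eigen-structure of the
    correlation matrix.  Eigenvalues are clipped at 0 and sorted
    descending; ratios sum to 1.
    """
    arr = np.asarray(pd.DataFrame(X), dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two rows")
    cov = np.cov(arr, rowvar=False, bias=True)
    cov = np.atleast_2d(cov)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    total = vals.sum()
    ratios = vals / total if total > 0 else np.zeros_like(vals)
    return PCAResult(eigenvalues=vals, loadings=vecs, explained_variance_ratio=ratios)


@dataclass(frozen=True)
class BorutaParams:
    """Boruta run parameters: forest size and depth, iteration cap,
    shadow-importance percentile, test level, holdout fraction."""

    n_estimators: int = 200
    max_iter: int = 300
    max_depth: int = 10
    shadow_percentile: float = 95.0
    alpha: float = 0.05
    holdout_fraction: float = 0.3


@dataclass(frozen=True)
class BorutaResult:
    """Per-feature decision plus the per-iteration importance trace."""

    decisions: dict[str, str]  # feature -> confirmed | tentative | rejected
    importance_history: pd.DataFrame
    params: BorutaParams
    n_iterations: int

    @property
    def confirmed(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "confirmed"]

    @property
    def tentative(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "tentative"]

    @property
    def rejected(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "rejected"]


def _name_rng(master_seed: int, iteration: int, name: str, replicate: int = 0) -> np.random.Generator:
    # substream keyed on the feature *name*, so reordering input columns
    # does not change any column's permutation stream
    key = zlib.crc32(str(name).encode()) & 0x7FFFFFFF
    return np.random.default_rng((master_seed, iteration, key, replicate))


def _fit_forest(Xf: np.ndarray, y: np.ndarray, params: BorutaParams, seed: int):
    p = Xf.shape[1]
    model = lgb.LGBMClassifier(
        boosting_type="rf",
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        subsample=0.632,
        subsample_freq=1,
        colsample_bytree=max(np.sqrt(p) / p, 2.0 / p),
        min_child_samples=5,
        n_jobs=1,
        random_state=seed,
        deterministic=True,
        verbose=-1,
    )
    model.fit(Xf, y)
    return model


def _holdout_permutation_importance(
    model, Xh: np.ndarray, yh: np.ndarray, columns: list[int], seeds: list[np.random.Generator]
) -> np.ndarray:
    """Drop in mean correct-class probability when each listed column of
    the holdout matrix is permuted (one batched predict call)."""
    n, p = Xh.shape
    k = len(columns)
    with warnings.catch_warnings():
        # lightgbm autonames ndarray columns; the name-mismatch warning on
        # predict is meaningless here
        warnings.simplefilter("ignore", UserWarning)
        base = model.predict_proba(Xh)[np.arange(n), yh].mean()
        big = np.repeat(Xh[None, :, :], k, axis=0)
        for slot, (j, rng) in enumerate(zip(columns, seeds)):
            big[slot, :, j] = rng.permutation(Xh[:, j])
        proba = model.predict_proba(big.reshape(k * n, p))[np.arange(k * n), np.tile(yh, k)]
    return base - proba.reshape(k, n).mean(axis=1)


def boruta_select(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    params: BorutaParams | None = None,
    seed: int = 0,
) -> BorutaResult:
    """All-relevant Boruta feature selection for a binary outcome.

    Iterates shadow-feature random forests until every feature is
    confirmed or rejected (or ``max_iter`` is reached; leftovers are
    tentative).  Rejected features are dropped from subsequent forests
    while the shadow pool is padded back to the original feature count.
    Features are processed in canonical (sorted-name) order and all
    permutation streams are keyed by feature name, so decisions are
    invariant to the column order of ``X``.
    """
    params = params or BorutaParams()
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("Boruta requires a binary outcome")
    if len(X) < 20:
        raise ValueError("need at least 20 rows")
    y01 = (y == classes[1]).astype(int)

    features = sorted(X.columns, key=str)  # canonical order
    nfeat = len(features)
    Xv = X[features].to_numpy(dtype=float)
    status = {f: "tentative" for f in features}
    hits = {f: 0 for f in features}
    history_rows = []
    master = np.random.default_rng(seed)

    it = 0
    while it < params.max_iter and any(status[f] == "tentative" for f in features):
        it += 1
        pos = {f: i for i, f in enumerate(features)}
        active = [f for f in features if status[f] != "rejected"]
        idx = [pos[f] for f in active]
        Xa = Xv[:, idx]

        # shadows: one permutation per active feature, padded with extra
        # independent permutations up to the original feature count
        n_shadow = max(len(active), nfeat)
        shadow_cols = []
        for k in range(n_shadow):
            name = active[k % len(active)]
            rng = _name_rng(seed, it, name, replicate=k // len(active))
            shadow_cols.append(rng.permutation(Xa[:, k % len(active)]))
        Xf = np.column_stack([Xa] + shadow_cols)

        order = master.permutation(len(y01))
        cut = max(int(round((1.0 - params.holdout_fraction) * len(y01))), 2)
        tri, tei = order[:cut], order[cut:]
        model = _fit_forest(Xf[tri], y01[tri], params, int(master.integers(2**31 - 1)))

        tentative_slots = [k for k, f in enumerate(active) if status[f] == "tentative"]
        shadow_slots = list(range(len(active), len(active) + n_shadow))
        eval_cols = tentative_slots + shadow_slots
        eval_rngs = [
            _name_rng(seed, it, active[c], replicate=1000) for c in tentative_slots
        ] + [
            _name_rng(seed, it, f"shadow{c}", replicate=1001) for c in shadow_slots
        ]
        imp = _holdout_permutation_importance(model, Xf[tei], y01[tei], eval_cols, eval_rngs)
        imp_real = dict(zip([active[c] for c in tentative_slots], imp[: len(tentative_slots)]))
        imp_shadow = imp[len(tentative_slots):]
        threshold = float(np.percentile(imp_shadow, params.shadow_percentile))

        for f, v in imp_real.items():
            if v > threshold:
                hits[f] += 1
        history_rows.append(
            {"iteration": it, "shadow_threshold": threshold,
             **{str(f): imp_real[f] for f in imp_real}}
        )

        # binomial tests on hit counts with the two-step correction:
        # step-up FDR combined with a Bonferroni bound on the raw p-values
        tent = [f for f in features if status[f] == "tentative"]
        h = np.array([hits[f] for f in tent], dtype=float)
        p_acc = sps.binom.sf(h - 1, it, 0.5)
        p_rej = sps.binom.cdf(h, it, 0.5)
        acc_fdr = multipletests(p_acc, alpha=params.alpha, method="fdr_bh")[0]
        rej_fdr = multipletests(p_rej, alpha=params.alpha, method="fdr_bh")[0]
        acc_bonf = p_acc <= params.alpha / it
        rej_bonf = p_rej <= params.alpha / it
        for f, a, r in zip(tent, acc_fdr & acc_bonf, rej_fdr & rej_bonf):
            if a:
                status[f] = "confirmed"
            elif r:
                status[f] = "rejected"

    undecided = [f for f in features if status[f] == "tentative"]
    if undecided:
        logger.info("Boruta left %d feature(s) tentative after %d iterations", len(undecided), it)

    decisions = {f: status[f] for f in X.columns}  # report in input order
    history = pd.DataFrame(history_rows)
    return BorutaResult(
        decisions=decisions, importance_history=history, params=params, n_iterations=it
    )
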