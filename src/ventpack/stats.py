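"""ROC statistics, correlated-AUC comparison and group tests.

The AUC is computed in its Mann-Whitney (midrank) form.  Two classifiers
scored on the *same* subjects are compared with the DeLong test: the
variance of the AUC difference is estimated from the per-subject
structural components of each ROC, which accounts for the correlation
induced by the shared sample.  Group comparisons gate on Shapiro-Wilk
normality, fall back to rank-sum tests, and adjust p-values with
Benjamini-Hochberg (step-up FDR) or Holm-Bonferroni (step-down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ROCComparison",
    "GroupComparisonRow",
    "auc_mann_whitney",
    "delong_test",
    "adjust_pvalues",
    "compare_groups",
    "correlate",
]

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class ROCComparison:
    """Paired-AUC contrast: AUCs, z statistic and two-sided p-value."""

    auc_a: float
    auc_b: float
    z: float
    p: float


@dataclass(frozen=True)
class GroupComparisonRow:
    """One variable's group means/SDs, the test used, raw and adjusted p."""

    variable: str
    group_stats: dict[str, tuple[float, float]]
    test: str
    p_raw: float
    p_adjusted: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("need both positive and negative labels")
    r = _midrank(scores)
    return float((r[labels].sum() - m * (m + 1) / 2) / (m * n))


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """Per-subject placement values V10 (positives) and V01 (negatives)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> ROCComparison:
    """DeLong comparison of two correlated AUCs on the same subjects.

    Identical score vectors (zero variance of the AUC difference) return
    z = 0, p = 1 with a warning.  Swapping the models negates z and leaves
    p unchanged.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be the same length (paired)")

    auc_a, v10_a, v01_a = _structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _structural_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)

    v10 = np.stack([v10_a, v10_b])
    v01 = np.stack([v01_a, v01_b])
    s10 = np.cov(v10, bias=False) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, bias=False) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var_diff <= 0:
        warnings.warn("zero variance of the AUC difference; returning p = 1")
        return ROCComparison(auc_a=float(auc_a), auc_b=float(auc_b), z=0.0, p=1.0)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return ROCComparison(auc_a=float(auc_a), auc_b=float(auc_b), z=float(z), p=float(min(p, 1.0)))


def adjust_pvalues(p_values, method: str = "benjamini_hochberg") -> np.ndarray:
    """Adjusted p-values: BH step-up FDR or Holm-Bonferroni step-down."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    key = {"benjamini_hochberg": "fdr_bh", "holm_bonferroni": "holm"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=key)[1]


def compare_groups(
    table: pd.DataFrame,
    variables: list[str],
    group_col: str = "label",
    adjust: str = "benjamini_hochberg",
) -> list[GroupComparisonRow]:
    """Per-variable two-group comparison with a Shapiro-Wilk gate.

    Variables normal in every group (Shapiro p > 0.05) get a two-sample
    t test (Welch); otherwise a Wilcoxon rank-sum test.  Raw p-values are
    adjusted across the variable set.  Variables constant in both groups
    are skipped with a NaN sentinel.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    rows = []
    raw_ps = []
    for var in variables:
        samples = [table.loc[table[group_col] == g, var].dropna().to_numpy(float) for g in groups]
        stats_by_group = {
            g: (float(np.mean(s)), float(np.std(s, ddof=1)) if len(s) > 1 else 0.0)
            for g, s in zip(groups, samples)
        }
        if all(np.ptp(s) == 0 for s in samples):
            rows.append((var, stats_by_group, "skipped_constant", float("nan")))
            raw_ps.append(np.nan)
            continue
        normal = True
        for s in samples:
            if len(s) >= 3 and np.ptp(s) > 0:
                if sps.shapiro(s).pvalue <= SHAPIRO_ALPHA:
                    normal = False
        if normal:
            test = "t"
            p = float(sps.ttest_ind(*samples, equal_var=False).pvalue)
        else:
            test = "ranksum"
            p = float(sps.mannwhitneyu(*samples, alternative="two-sided").pvalue)
        rows.append((var, stats_by_group, test, p))
        raw_ps.append(p)

    raw = np.asarray(raw_ps, dtype=float)
    adj = np.full_like(raw, np.nan)
    ok = ~np.isnan(raw)
    if ok.any():
        adj[ok] = adjust_pvalues(raw[ok], adjust)
    return [
        GroupComparisonRow(variable=v, group_stats=gs, test=t, p_raw=p, p_adjusted=float(a))
        for (v, gs, t, p), a in zip(rows, adj)
    ]


def correlate(x, y, method: str = "auto") -> tuple[float, float]:
    """Correlation coefficient and p-value.

    ``auto`` uses Pearson when both variables pass the Shapiro-Wilk
    normality gate and Spearman otherwise; ``pearson``/``spearman`` force
    the choice.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "auto":
        normal = True
        for s in (x, y):
            if np.ptp(s) == 0:
                normal = False
            elif len(s) >= 3 and sps.shapiro(s).pvalue <= SHAPIRO_ALPHA:
                normal = False
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)
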