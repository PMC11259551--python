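import numpy as np
import pandas as pd
import pytest

from ventpack.stats import (
    adjust_pvalues,
    auc_mann_whitney,
    compare_groups,
    correlate,
    delong_test,
)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_mann_whitney([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_null_distribution(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=200)
            labels = np.array([0, 1] * 100)
            aucs.append(auc_mann_whitney(scores, labels))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_matches_trapezoidal_roc_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 20))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            thresholds = np.unique(scores)[::-1]
            pts = [(0.0, 0.0)]
            for t in thresholds:
                pred = scores >= t
                tpr = (pred & labels).sum() / labels.sum()
                fpr = (pred & ~labels).sum() / (~labels).sum()
                pts.append((fpr, tpr))
            pts.append((1.0, 1.0))
            pts = sorted(set(pts))
            area = np.trapezoid([p[1] for p in pts], [p[0] for p in pts])
            assert auc_mann_whitney(scores, labels) == pytest.approx(area, abs=1e-12)


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        scores = rng.normal(size=40)
        labels = np.array([0, 1] * 20)
        with pytest.warns(UserWarning, match="zero variance"):
            cmp_ = delong_test(scores, scores, labels)
        assert cmp_.p == 1.0
        assert cmp_.z == 0.0

    def test_antisymmetry(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        r1 = delong_test(a, b, labels)
        r2 = delong_test(b, a, labels)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_small_sample_agrees_with_bootstrap_oracle(self):
        rng = np.random.default_rng(3)
        labels = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        a = labels + rng.normal(0, 0.8, 12)
        b = rng.normal(0, 1, 12)
        res = delong_test(a, b, labels)
        # paired bootstrap over subjects
        diffs = []
        for _ in range(10_000):
            idx = rng.integers(0, 12, 12)
            la = labels[idx]
            if la.all() or not la.any():
                continue
            diffs.append(auc_mann_whitney(a[idx], la) - auc_mann_whitney(b[idx], la))
        diffs = np.asarray(diffs)
        p_boot = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert res.p == pytest.approx(p_boot, abs=0.05)

    def test_variance_reduces_to_single_auc_limit(self, rng):
        """Comparing a model with itself plus vanishing independent noise:
        the difference variance tends to zero, i.e. the covariance term
        approaches the single-AUC variance."""
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.5).astype(int)
        labels[:2] = [0, 1]
        zs = []
        for eps in (1e-3, 1e-5):
            noisy = scores + eps * rng.normal(size=100)
            res = delong_test(scores, noisy, labels)
            zs.append(abs(res.auc_a - res.auc_b))
        assert zs[1] <= zs[0] + 1e-9


class TestAdjustPvalues:
    def test_bh_hand_example(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "benjamini_hochberg")
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_holm_hand_example(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "holm_bonferroni")
        assert np.allclose(adj, [0.04, 0.06, 0.06, 0.06])

    def test_single_p_unchanged(self):
        for method in ("benjamini_hochberg", "holm_bonferroni"):
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_monotone_and_bounded(self, rng):
        for method in ("benjamini_hochberg", "holm_bonferroni"):
            p = np.sort(rng.random(15))
            adj = adjust_pvalues(p, method)
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= 1.0)
            assert np.all(np.diff(adj) >= -1e-12)  # monotone in sorted order


class TestCompareGroups:
    def _table(self, rng, shift=0.0, n=40):
        return pd.DataFrame(
            {
                "label": ["a"] * n + ["b"] * n,
                "x": np.concatenate([rng.normal(0, 1, n), rng.normal(shift, 1, n)]),
                "const": 1.0,
            }
        )

    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats as sps

        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rows = compare_groups(self._table(rng), ["x"])
            ps.append(rows[0].p_raw)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            rows = compare_groups(self._table(rng, shift=2.0), ["x"])
            hits += rows[0].p_adjusted < 0.05
        assert hits >= 38  # >= 95% power at a 2 SD shift

    def test_constant_variable_skipped(self, rng):
        rows = compare_groups(self._table(rng), ["x", "const"])
        by_var = {r.variable: r for r in rows}
        assert by_var["const"].test == "skipped_constant"
        assert np.isnan(by_var["const"].p_raw)
        assert by_var["x"].p_adjusted >= by_var["x"].p_raw - 1e-12

    def test_nonnormal_gate_uses_ranksum(self, rng):
        n = 60
        table = pd.DataFrame(
            {
                "label": ["a"] * n + ["b"] * n,
                "x": np.concatenate([rng.exponential(1, n), rng.exponential(1, n) + 1]),
            }
        )
        rows = compare_groups(table, ["x"])
        assert rows[0].test == "ranksum"


class TestCorrelate:
    def test_identity_spearman(self):
        x = np.arange(20, dtype=float)
        rho, _ = correlate(x, x, method="spearman")
        assert rho == 1.0

    def test_monotone_transform_rank_invariance(self):
        x = np.linspace(0.1, 3.0, 25)
        y = -np.exp(x)  # monotone decreasing transform of x
        rho, _ = correlate(x, y, method="spearman")
        assert rho == -1.0

    def test_bivariate_normal_estimate(self):
        rng = np.random.default_rng(0)
        cov = [[1.0, 0.5], [0.5, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=500)
        rho, p = correlate(xy[:, 0], xy[:, 1])
        assert rho == pytest.approx(0.5, abs=0.1)
        assert p < 1e-6
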