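"""LDA, ROC/AUC, DeLong intervals, and the nested LOOCV engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import retispec as rs
from retispec.classify import DegenerateLabelError


def _two_gaussians(rng, n_pos, n_neg, p, delta):
    X = rng.standard_normal((n_pos + n_neg, p))
    X[:n_pos] += delta
    y = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(int)
    return X, y


class TestLDA:
    def test_symmetric_one_dimensional_problem(self):
        X = np.array([[1.0], [1.5], [0.5], [-1.0], [-1.5], [-0.5]])
        y = np.array([1, 1, 1, 0, 0, 0])
        model = rs.fit_lda(X, y)
        assert rs.predict_proba(model, np.array([0.0])) == pytest.approx(0.5)
        assert rs.predict_proba(model, np.array([10.0])) > 0.999

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelError):
            rs.fit_lda(np.random.default_rng(0).random((6, 2)), np.ones(6))

    def test_collinear_features_handled_by_shrinkage(self):
        rng = np.random.default_rng(1)
        X, y = _two_gaussians(rng, 10, 10, 3, 1.0)
        dup = np.hstack([X, X[:, :1]])  # exact duplicate column
        p_single = rs.predict_proba(rs.fit_lda(X, y), X)
        p_dup = rs.predict_proba(rs.fit_lda(dup, y), dup)
        assert np.max(np.abs(p_single - p_dup)) < 1e-3

    def test_posteriors_match_reference_implementation(self):
        """Posteriors agree with scikit-learn LDA within 1e-6 on 20 datasets."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(0)
        for _ in range(20):
            X, y = _two_gaussians(rng, 10, 10, 5, rng.uniform(0.2, 0.8))
            mine = rs.predict_proba(rs.fit_lda(X, y), X)
            ref = sklearn.LinearDiscriminantAnalysis().fit(X, y).predict_proba(X)[:, 1]
            assert np.max(np.abs(mine - ref)) < 1e-6

    def test_probabilities_complement(self):
        rng = np.random.default_rng(2)
        X, y = _two_gaussians(rng, 8, 12, 4, 0.5)
        p_pos = rs.predict_proba(rs.fit_lda(X, y), X)
        p_neg = rs.predict_proba(rs.fit_lda(X, 1 - y), X)
        assert np.all((p_pos >= 0) & (p_pos <= 1))
        assert np.allclose(p_pos + p_neg, 1.0, atol=1e-9)

    def test_affine_invariance(self):
        """An invertible affine map of all features leaves posteriors unchanged."""
        rng = np.random.default_rng(3)
        X, y = _two_gaussians(rng, 10, 10, 4, 0.6)
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        b = rng.standard_normal(4)
        Xt = X @ A.T + b
        p0 = rs.predict_proba(rs.fit_lda(X, y), X)
        p1 = rs.predict_proba(rs.fit_lda(Xt, y), Xt)
        assert np.max(np.abs(p0 - p1)) < 1e-6

    def test_dimension_mismatch_rejected(self):
        model = rs.fit_lda(np.random.default_rng(0).random((8, 3)),
                           np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        with pytest.raises(ValueError):
            rs.predict_proba(model, np.ones(5))


class TestAUC:
    def test_perfect_and_degenerate(self):
        y = np.array([1, 1, 0, 0])
        assert rs.roc_auc([0.9, 0.8, 0.2, 0.1], y) == 1.0
        assert rs.roc_auc([0.5, 0.5, 0.5, 0.5], y) == 0.5

    def test_hand_counted_pairs(self):
        """(0.9,+), (0.8,−), (0.4,+), (0.3,−): 3 of 4 pairs concordant."""
        assert rs.roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.integers(2, 12), st.integers(0, 10_000))
    def test_auc_equals_mann_whitney_u(self, n_pos, n_neg, seed):
        """AUC = U / (n+ n-) exactly on tie-free data."""
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.arange(n_pos + n_neg, dtype=float))
        y = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(int)
        u = sps.mannwhitneyu(scores[y == 1], scores[y == 0],
                             alternative="two-sided").statistic
        assert rs.roc_auc(scores, y) == pytest.approx(u / (n_pos * n_neg), abs=1e-12)

    def test_roc_curve_endpoints(self):
        fpr, tpr, _ = rs.roc_curve([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelError):
            rs.roc_auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_perfect_separation_degenerate_interval(self):
        y = np.array([1, 1, 0, 0])
        assert rs.delong_ci([0.9, 0.8, 0.2, 0.1], y) == (1.0, 1.0)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            y = np.r_[np.ones(12), np.zeros(15)].astype(int)
            s = rng.standard_normal(27) + 0.7 * y
            lo, hi = rs.delong_ci(s, y)
            assert lo <= rs.roc_auc(s, y) <= hi

    def test_width_matches_bootstrap(self):
        """Mean DeLong width within 15% of a 2000-replicate bootstrap width."""
        rng = np.random.default_rng(42)
        ratios = []
        for _ in range(200):
            y = np.r_[np.ones(17), np.zeros(23)].astype(int)
            s = rng.standard_normal(40) + 0.8 * y
            dlo, dhi = rs.delong_ci(s, y)
            blo, bhi = rs.bootstrap_ci(s, y, n_boot=2000, rng=rng)
            ratios.append((dhi - dlo) / (bhi - blo))
        assert abs(np.mean(ratios) - 1.0) < 0.15


class TestInnerLOOCV:
    def test_null_features_near_chance(self):
        """Label-independent features give mean LOO AUC near 0.5."""
        rng = np.random.default_rng(6)
        aucs = [
            rs.inner_loocv_auc(*_two_gaussians(rng, 20, 20, 5, 0.0))
            for _ in range(200)
        ]
        assert 0.40 <= np.mean(aucs) <= 0.60

    def test_strong_effect_high_auc(self):
        rng = np.random.default_rng(7)
        X, y = _two_gaussians(rng, 20, 20, 5, 3.0)
        assert rs.inner_loocv_auc(X, y) >= 0.95

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        X, y = _two_gaussians(rng, 10, 12, 6, 0.4)
        assert rs.inner_loocv_auc(X, y) == rs.inner_loocv_auc(X, y)


class TestNestedLOOCV:
    def _feature_sets(self, rng, n_ad=17, n_ctrl=22, delta=0.0, signal_config=None):
        n = n_ad + n_ctrl
        y = np.r_[np.ones(n_ad), np.zeros(n_ctrl)].astype(int)
        fs = {
            "S1": rng.standard_normal((n, 14)),
            "I2": rng.standard_normal((n, 14)),
            "S1+RNFL": rng.standard_normal((n, 19)),
            "I2+RNFL": rng.standard_normal((n, 19)),
        }
        if signal_config:
            fs[signal_config][y == 1, :5] += delta
        return fs, y

    def test_one_fold_and_selection_per_subject(self):
        rng = np.random.default_rng(9)
        fs, y = self._feature_sets(rng)
        res = rs.nested_loocv(fs, y)
        assert len(res.selected_configs) == 39
        assert len(res.probabilities) == 39
        assert np.all((res.probabilities >= 0) & (res.probabilities <= 1))
        assert sum(res.selection_tally.values()) == 39

    def test_selection_consistency_under_strong_effect(self):
        """A config carrying the only real effect wins ≥ 90% of outer folds."""
        rng = np.random.default_rng(10)
        fs, y = self._feature_sets(rng, delta=1.5, signal_config="I2+RNFL")
        res = rs.nested_loocv(fs, y)
        assert res.selection_tally.get("I2+RNFL", 0) >= 0.9 * 39
        assert res.outer_auc > 0.8

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        fs, y = self._feature_sets(rng, delta=0.5, signal_config="S1")
        a = rs.nested_loocv(fs, y)
        b = rs.nested_loocv(fs, y)
        assert a.outer_auc == b.outer_auc
        assert a.selected_configs == b.selected_configs
        assert a.ci == b.ci

    def test_config_filter_restricts_candidates(self):
        rng = np.random.default_rng(12)
        fs, y = self._feature_sets(rng)
        res = rs.nested_loocv(fs, y, config_filter=lambda idx: ["S1", "I2"])
        assert set(res.selected_configs) <= {"S1", "I2"}
        assert len(res.per_fold_allowed) == 39

    def test_bootstrap_ci_option(self):
        rng = np.random.default_rng(13)
        fs, y = self._feature_sets(rng, n_ad=6, n_ctrl=7, delta=1.0,
                                   signal_config="S1")
        fs = {"S1": fs["S1"]}
        res = rs.nested_loocv(fs, y, ci_method="bootstrap", n_boot=200,
                              rng=np.random.default_rng(0))
        assert res.ci[0] <= res.outer_auc + 1e-9
        assert res.ci_method == "bootstrap"
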