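"""Group-comparison statistics, adjusted RNFL effects, and the SEM screen."""

import numpy as np
import pytest
from scipy import stats as sps

import retispec as rs
from retispec.stats import CollinearityError, StatsParameterError, group_spectral_summary


class TestPooledT:
    def test_printed_age_summaries(self):
        """Age 71.9±6.6 (n=17) vs 68.6±8.4 (n=22) is non-significant, p≈0.19."""
        res = rs.pooled_t_test_summary(71.9, 6.6, 17, 68.6, 8.4, 22)
        assert res.df == 37
        assert res.p == pytest.approx(0.193, abs=0.01)

    def test_identical_groups(self):
        res = rs.pooled_t_test_summary(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_scipy_summary_oracle(self):
        res = rs.pooled_t_test_summary(10, 2, 5, 8, 2, 5)
        oracle = sps.ttest_ind_from_stats(10, 2, 5, 8, 2, 5, equal_var=True)
        assert res.statistic == pytest.approx(1.581, abs=1e-3)
        assert res.df == 8
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-12)
        assert res.p == pytest.approx(0.153, abs=5e-4)

    def test_invalid_inputs(self):
        with pytest.raises(StatsParameterError):
            rs.pooled_t_test_summary(1, 1, 1, 2, 1, 5)
        with pytest.raises(StatsParameterError):
            rs.pooled_t_test_summary(1, 0, 5, 2, 1, 5)


class TestMannWhitney:
    def test_identical_multisets_give_p_one(self):
        res = rs.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 2/20 = 0.1."""
        res = rs.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_large_separation_significant(self):
        rng = np.random.default_rng(0)
        res = rs.mann_whitney(rng.normal(0, 1, 40), rng.normal(5, 1, 40))
        assert res.p < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsParameterError):
            rs.mann_whitney([], [1.0])


class TestChiSquare:
    def test_eye_laterality_table(self):
        res = rs.chi_square_2x2([[10, 7], [10, 12]])
        assert res.p == pytest.approx(0.408, abs=0.002)

    def test_phakia_table(self):
        res = rs.chi_square_2x2([[15, 2], [12, 10]])
        assert res.p == pytest.approx(0.024, abs=0.002)

    def test_balanced_table_null(self):
        res = rs.chi_square_2x2([[5, 5], [5, 5]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_transpose_and_label_swap_invariance(self):
        t = np.array([[13, 4], [6, 11]])
        p0 = rs.chi_square_2x2(t).p
        assert rs.chi_square_2x2(t.T).p == pytest.approx(p0)
        assert rs.chi_square_2x2(t[::-1, ::-1]).p == pytest.approx(p0)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsParameterError):
            rs.chi_square_2x2([[0, 0], [3, 4]])


class TestAdjustedGroupEffect:
    def test_parameter_recovery_with_confounding(self):
        """The group coefficient recovers the true effect within 3 SE."""
        rng = np.random.default_rng(4)
        n, delta = 400, 5.0
        group = (rng.random(n) < 0.5).astype(float)
        age = 65 + 5 * rng.standard_normal(n) + 3 * group  # confounded covariate
        gender = (rng.random(n) < 0.5).astype(float)
        quality = 60 + 8 * rng.standard_normal(n) - 2 * group
        y = 90 - 0.4 * age + 2 * gender + 0.1 * quality + delta * group \
            + rng.normal(0, 4, n)
        res = rs.adjusted_group_effect(y, group, age, gender, quality)
        se = abs(res.estimate / res.statistic)
        assert abs(res.estimate - delta) < 3 * se

    def test_no_group_effect(self):
        rng = np.random.default_rng(7)
        n = 200
        group = np.r_[np.ones(100), np.zeros(100)]
        age = rng.normal(70, 6, n)
        y = age * 1.2 + rng.normal(0, 1, n)  # depends on covariates only
        res = rs.adjusted_group_effect(
            y, group, age, (rng.random(n) < 0.5).astype(float), rng.normal(60, 5, n)
        )
        se = abs(res.estimate / res.statistic)
        assert abs(res.estimate) < 3 * se and res.p > 0.01

    def test_matches_normal_equations_oracle(self):
        """Six-point dataset solved via the normal equations by hand."""
        y = np.array([10.0, 12.0, 9.0, 14.0, 11.0, 13.0])
        group = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        age = np.array([60.0, 62.0, 65.0, 61.0, 66.0, 63.0])
        gender = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        quality = np.array([50.0, 55.0, 48.0, 60.0, 52.0, 58.0])
        X = np.column_stack([np.ones(6), group, age, gender, quality])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        df = 6 - 5
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        t = beta[1] / np.sqrt(cov[1, 1])
        p = 2 * sps.t.sf(abs(t), df)
        res = rs.adjusted_group_effect(y, group, age, gender, quality)
        assert res.estimate == pytest.approx(beta[1], rel=1e-9)
        assert res.statistic == pytest.approx(t, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)
        assert res.df == df

    def test_collinear_design_rejected(self):
        n = 20
        group = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(CollinearityError):
            rs.adjusted_group_effect(np.arange(n, dtype=float), group, group, group,
                                     np.ones(n))


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert rs.bonferroni([0.01], 5)[0] == pytest.approx(0.05)
        assert rs.bonferroni([0.5], 5)[0] == 1.0

    def test_rnfl_significance_pattern(self):
        """With m=5, only the 0.005 and 0.009 RNFL p-values stay below 0.05."""
        raw = {"AVG": 0.005, "SUP": 0.019, "INF": 0.009, "TEM": 0.069, "NAS": 0.012}
        adjusted = rs.bonferroni(list(raw.values()), m=5)
        significant = {k for k, p in zip(raw, adjusted) if p < 0.05}
        assert significant == {"AVG", "INF"}

    def test_monotone_order_preserving(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.random(8))
        adj = rs.bonferroni(p, 10)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= p)


def _correlated_roi_cohort(rng, delta=0.03):
    """Per-ROI subject spectra with one shared smooth noise mode and a
    short-wavelength AD effect concentrated in S1 and I2."""
    n_ad, n_ctrl, nb = 17, 22, 14
    mode = np.linspace(-1, 1, nb)
    effect = np.clip(1 - np.arange(nb) / 6, 0, None)
    labels = np.r_[np.ones(n_ad), np.zeros(n_ctrl)].astype(int)
    rois = {}
    for rid in ("S1", "S2", "I1", "I2"):
        spec = 1 + rng.normal(0, 0.02, (n_ad + n_ctrl, 1)) * mode
        spec += rng.normal(0, 0.001, (n_ad + n_ctrl, nb))
        if rid in ("S1", "I2"):
            spec[:n_ad] += delta * effect
        rois[rid] = spec
    return rois, labels


class TestSemScreen:
    def test_identical_spectra_select_nothing(self):
        spectra = np.tile(np.linspace(0.9, 1.1, 14), (20, 1))
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        assert rs.sem_screen({"S1": spectra}, labels) == []

    def test_clear_separation_selects(self):
        rng = np.random.default_rng(3)
        spectra = 1 + rng.normal(0, 0.001, (20, 14))
        spectra[:10, 2] += 0.05  # one band far beyond SEM overlap
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        assert rs.sem_screen({"I2": spectra}, labels) == ["I2"]
        summary = group_spectral_summary(spectra, labels, "I2")
        assert 2 in summary.nonoverlap_bands()

    def test_concentrated_effect_selects_strict_subset(self):
        """Effect confined to S1/I2 yields a strict subset in most replicates."""
        rng = np.random.default_rng(12)
        strict = effect_found = 0
        n_rep = 40
        for _ in range(n_rep):
            rois, labels = _correlated_roi_cohort(rng)
            sel = rs.sem_screen(rois, labels)
            strict += 0 < len(sel) < 4
            effect_found += {"S1", "I2"} <= set(sel)
        assert strict >= 0.7 * n_rep
        assert effect_found >= 0.9 * n_rep

    def test_small_group_rejected(self):
        labels = np.r_[np.ones(1), np.zeros(5)].astype(int)
        with pytest.raises(StatsParameterError):
            rs.sem_screen({"S1": np.ones((6, 14))}, labels)


def test_table2_report_structure(cohort):
    table = rs.table2_report(rs.cohort_to_frame(cohort))
    assert set(table.columns) == {"variable", "ad", "ctrl", "test", "p", "p_adjusted"}
    rnfl = table[table["variable"].str.startswith("rnfl")]
    assert len(rnfl) == 5
    assert (rnfl["p_adjusted"] >= rnfl["p"] - 1e-12).all()
    assert table["p"].between(0, 1).all()
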