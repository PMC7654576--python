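"""Cohort statistics: group comparisons, covariate-adjusted RNFL
effects, Bonferroni correction, and the SEM-overlap ROI screen.

The battery mirrors standard clinical-study reporting for an
AD-versus-control cohort: pooled-variance t tests for continuous
variables, Mann-Whitney for ordinal ones, Pearson chi-square (without
continuity correction) for dichotomous ones, and ordinary least squares
to adjust the RNFL group effect for age, gender and scan quality, with
a Bonferroni correction over the five RNFL parameters.

The SEM screen is the region-selection rule used before classifier
model selection: an ROI enters the candidate set only if the AD and
control mean spectra, each bracketed by +-1 standard error of the mean,
fail to overlap at one or more wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "GroupSpectralSummary",
    "StatsParameterError",
    "CollinearityError",
    "pooled_t_test_summary",
    "mann_whitney",
    "chi_square_2x2",
    "adjusted_group_effect",
    "bonferroni",
    "group_spectral_summary",
    "sem_screen",
    "table2_report",
]


class StatsParameterError(ValueError):
    """Invalid sample sizes, SDs or table margins."""


class CollinearityError(ValueError):
    """Rank-deficient regression design."""


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p: float
    df: float | None = None
    p_adjusted: float | None = None
    estimate: float | None = None  # e.g. adjusted group difference


@dataclass
class GroupSpectralSummary:
    """Per-band group means and standard errors for one ROI."""

    roi_id: str
    band_index: np.ndarray
    mean_ad: np.ndarray
    sem_ad: np.ndarray
    mean_ctrl: np.ndarray
    sem_ctrl: np.ndarray

    def nonoverlap_bands(self, multiplier: float = 1.0) -> np.ndarray:
        """Indices of bands where the mean +- multiplier*SEM intervals are disjoint."""
        gap = np.abs(self.mean_ad - self.mean_ctrl)
        return np.flatnonzero(gap > multiplier * (self.sem_ad + self.sem_ctrl))


def pooled_t_test_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> StatResult:
    """Two-sample pooled-variance t test from summary statistics.

    ``t = (m1 - m2) / (sp * sqrt(1/n1 + 1/n2))`` with the pooled SD
    ``sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)``; two-sided p
    on ``n1 + n2 - 2`` degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise StatsParameterError("need n >= 2 in each group")
    if s1 <= 0 or s2 <= 0:
        raise StatsParameterError("SDs must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult("pooled t", float(t), float(p), df=df, estimate=m1 - m2)


def mann_whitney(x, y) -> StatResult:
    """Mann-Whitney U test, two-sided.

    Exact enumeration when ``n1 * n2 <= 400`` and the pooled sample has
    no ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= 400 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return StatResult("Mann-Whitney U", float(res.statistic), float(min(res.pvalue, 1.0)))


def chi_square_2x2(table) -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise StatsParameterError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise StatsParameterError("table must hold non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise StatsParameterError("all margins must be positive")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return StatResult("chi-square", float(chi2), float(p), df=float(df))


def adjusted_group_effect(y, group, age, gender, quality) -> StatResult:
    """Group effect on ``y`` adjusted for age, gender and scan quality.

    Ordinary least squares of y on an intercept, the group indicator and
    the three covariates; returns the group coefficient with its t
    statistic and two-sided p on ``n - 5`` degrees of freedom.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    X = np.column_stack(
        [
            group,
            np.asarray(age, dtype=float),
            np.asarray(gender, dtype=float),
            np.asarray(quality, dtype=float),
        ]
    )
    n = y.size
    if n <= X.shape[1] + 1:
        raise StatsParameterError("n must exceed the number of predictors + 1")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("regression design is rank-deficient")
    fit = sm.OLS(y, design).fit()
    return StatResult(
        "adjusted group effect (OLS)",
        statistic=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        df=float(fit.df_resid),
        estimate=float(fit.params[1]),
    )


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise StatsParameterError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def group_spectral_summary(
    spectra: np.ndarray, labels: np.ndarray, roi_id: str = ""
) -> GroupSpectralSummary:
    """Per-band AD/control means and SEMs from per-subject ROI spectra.

    ``spectra`` is ``(n_subjects, n_bands)``; ``labels`` is 1 for AD and
    0 for control.
    """
    spectra = np.asarray(spectra, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_ad, n_ctrl = int(labels.sum()), int((~labels).sum())
    if n_ad < 2 or n_ctrl < 2:
        raise StatsParameterError("need >= 2 subjects per group")
    ad, ctrl = spectra[labels], spectra[~labels]
    return GroupSpectralSummary(
        roi_id=roi_id,
        band_index=np.arange(spectra.shape[1]),
        mean_ad=ad.mean(axis=0),
        sem_ad=ad.std(axis=0, ddof=1) / np.sqrt(n_ad),
        mean_ctrl=ctrl.mean(axis=0),
        sem_ctrl=ctrl.std(axis=0, ddof=1) / np.sqrt(n_ctrl),
    )


def sem_screen(
    roi_spectra: dict[str, np.ndarray],
    labels: np.ndarray,
    multiplier: float = 1.0,
) -> list[str]:
    """Select the ROIs whose group mean spectra separate beyond SEM.

    ``roi_spectra`` maps ROI id -> ``(n_subjects, n_bands)`` array of
    per-subject spectra (same subject order everywhere).  An ROI is
    selected iff the AD and control ``mean +- multiplier*SEM`` intervals
    are disjoint at one or more bands.
    """
    selected = []
    for roi_id, spectra in roi_spectra.items():
        summary = group_spectral_summary(spectra, labels, roi_id)
        if summary.nonoverlap_bands(multiplier).size > 0:
            selected.append(roi_id)
    return selected


# ---------------------------------------------------------------------------
# Cohort characteristics report
# ---------------------------------------------------------------------------

_CONTINUOUS = ["age", "bmi", "bcva", "iop", "vcdr"]
_RNFL_COLS = ["rnfl_avg", "rnfl_sup", "rnfl_inf", "rnfl_tem", "rnfl_nas"]


def table2_report(cohort):
    """Cohort-characteristics table as a pandas DataFrame.

    One row per variable with group means +- SD (or counts), the test
    used, the p-value, and the Bonferroni-adjusted p for the five RNFL
    parameters.  ``cohort`` is the DataFrame from
    :func:`retispec.synthetic.cohort_to_frame`.
    """
    import pandas as pd

    ad = cohort[cohort["group"] == "AD"]
    ctrl = cohort[cohort["group"] == "CTRL"]
    rows = []

    def _ms(series):
        return f"{series.mean():.1f} ± {series.std(ddof=1):.1f}"

    for var in _CONTINUOUS:
        res = pooled_t_test_summary(
            ad[var].mean(), ad[var].std(ddof=1), len(ad),
            ctrl[var].mean(), ctrl[var].std(ddof=1), len(ctrl),
        )
        rows.append((var, _ms(ad[var]), _ms(ctrl[var]), res.test_name, res.p, None))

    res = mann_whitney(ad["mmse"], ctrl["mmse"])
    rows.append(("mmse", _ms(ad["mmse"]), _ms(ctrl["mmse"]), res.test_name, res.p, None))

    for var, level in (("sex", "M"), ("eye", "right"), ("phakic", True)):
        tab = np.array(
            [
                [int((ad[var] == level).sum()), int((ad[var] != level).sum())],
                [int((ctrl[var] == level).sum()), int((ctrl[var] != level).sum())],
            ]
        )
        desc_ad = f"{tab[0, 0]}/{tab[0, 1]}"
        desc_ctrl = f"{tab[1, 0]}/{tab[1, 1]}"
        try:
            res = chi_square_2x2(tab)
            rows.append((var, desc_ad, desc_ctrl, res.test_name, res.p, None))
        except StatsParameterError:
            # degenerate margin (can happen in very small cohorts)
            rows.append((var, desc_ad, desc_ctrl, "chi-square (degenerate)",
                         np.nan, None))

    gender = (cohort["sex"] == "M").astype(float).to_numpy()
    group = (cohort["group"] == "AD").astype(float).to_numpy()
    raw_p = []
    rnfl_rows = []
    for var in _RNFL_COLS:
        res = adjusted_group_effect(
            cohort[var].to_numpy(), group, cohort["age"].to_numpy(),
            gender, cohort["scan_quality"].to_numpy(),
        )
        raw_p.append(res.p)
        rnfl_rows.append((var, _ms(ad[var]), _ms(ctrl[var]), res.test_name, res.p))
    adj = bonferroni(raw_p, m=len(_RNFL_COLS))
    for (var, a, c, name, p), pa in zip(rnfl_rows, adj):
        rows.append((var, a, c, name, p, pa))

    return pd.DataFrame(
        rows, columns=["variable", "ad", "ctrl", "test", "p", "p_adjusted"]
    )
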