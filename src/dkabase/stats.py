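"""Two-group comparison battery, LOS correlation/regression, and t-test power.

Continuous variables are compared with Student's t-test when both groups pass
a Shapiro–Wilk normality check, otherwise with the Mann–Whitney U test;
categorical variables use chi-square, or Fisher's exact test when any
expected cell count falls below 5.  The ICU length of stay is related to the
6-hour delta variables by Pearson correlation and by an ordinary
least-squares model with per-coefficient 95% confidence intervals, R² and
the Durbin–Watson statistic.  No multiple-testing correction is applied; the
report output records this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson

from .errors import CollinearityError, DegenerateDataError, DomainError

__all__ = [
    "ComparisonResult",
    "RegressionResult",
    "choose_test",
    "choose_categorical_test",
    "compare_groups",
    "correlate_with_los",
    "los_regression",
    "two_sample_t_power",
    "DEFAULT_PREDICTORS",
]

STUDENT_T = "student_t"
MANN_WHITNEY = "mann_whitney"
CHI_SQUARE = "chi_square"
FISHER_EXACT = "fisher_exact"

#: Shapiro–Wilk p-value below which a group is treated as non-normal.
NORMALITY_ALPHA = 0.05

#: Predictors of the LOS model: demographics/severity plus the 6-hour deltas.
#: delta_ph enters scaled by 100 (per 0.01 pH unit) so its coefficient is on
#: a comparable magnitude to the electrolyte deltas.
DEFAULT_PREDICTORS = (
    "age", "bmi", "apache2", "sofa",
    "delta_ph", "delta_paco2", "delta_hco3", "delta_na", "delta_cl",
    "delta_lactate", "delta_sig", "delta_glucose",
)


@dataclass
class ComparisonResult:
    variable: str
    test_used: str
    statistic: float
    p_value: float
    group_summaries: Dict[str, str] = field(default_factory=dict)


@dataclass
class RegressionResult:
    outcome: str
    table: pd.DataFrame  # index: predictor; columns: coef, ci_low, ci_high, p_value
    r_squared: float
    durbin_watson: float
    n: int


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def choose_test(values_g1, values_g2) -> str:
    """Normality-gated test choice for a continuous variable.

    Student's t when Shapiro–Wilk p >= 0.05 in both groups, otherwise
    Mann–Whitney U.  Requires at least three observations per group.
    """
    g1, g2 = _clean(values_g1), _clean(values_g2)
    if len(g1) < 3 or len(g2) < 3:
        raise DegenerateDataError(
            f"need >= 3 observations per group, got {len(g1)} and {len(g2)}")
    for g in (g1, g2):
        if np.ptp(g) == 0:
            # Shapiro is undefined on a constant sample; constants are
            # certainly non-normal for gating purposes.
            return MANN_WHITNEY
        if sps.shapiro(g).pvalue < NORMALITY_ALPHA:
            return MANN_WHITNEY
    return STUDENT_T


def choose_categorical_test(table) -> str:
    """Chi-square, or Fisher's exact when any expected count is below 5."""
    table = np.asarray(table, dtype=float)
    if table.sum() <= 0:
        raise DegenerateDataError("empty contingency table")
    expected = sps.contingency.expected_freq(table)
    return FISHER_EXACT if (expected < 5).any() else CHI_SQUARE


def _summary(values: np.ndarray, test: str) -> str:
    if test == STUDENT_T:
        return f"{np.mean(values):.1f} ± {np.std(values, ddof=1):.1f}"
    return (f"{np.median(values):.1f} "
            f"({np.min(values):.1f}–{np.max(values):.1f})")


def compare_groups(
    df: pd.DataFrame,
    variable: str,
    group_col: str = "group_label",
    categorical: bool = False,
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sided two-group comparison of one cohort variable.

    Continuous variables go through :func:`choose_test`; categorical ones
    through :func:`choose_categorical_test` on the group-by-level
    contingency table.  ``equal_var=False`` switches the t-test to Welch.
    """
    if variable not in df.columns:
        raise DomainError(f"unknown variable: {variable}")
    groups = [g for g, _ in df.groupby(group_col, sort=True)]
    if len(groups) != 2:
        raise DegenerateDataError(
            f"need exactly 2 groups in {group_col!r}, found {groups}")
    if categorical:
        table = pd.crosstab(df[group_col], df[variable]).to_numpy()
        test = choose_categorical_test(table)
        if test == FISHER_EXACT and table.shape == (2, 2):
            stat, p = sps.fisher_exact(table)
        elif test == FISHER_EXACT:
            # General r x c exact tests are not defined here; fall back to
            # chi-square with a note in the statistic name.
            stat, p, _, _ = sps.chi2_contingency(table)
        else:
            stat, p, _, _ = sps.chi2_contingency(table)
        summaries = {
            str(g): " / ".join(
                f"{lvl}: {cnt}" for lvl, cnt in
                df.loc[df[group_col] == g, variable].value_counts().items())
            for g in groups
        }
        return ComparisonResult(variable, test, float(stat), float(p), summaries)

    g1 = _clean(df.loc[df[group_col] == groups[0], variable])
    g2 = _clean(df.loc[df[group_col] == groups[1], variable])
    if np.ptp(g1) == 0 and np.ptp(g2) == 0 and (len(g1) and len(g2)) \
            and g1[0] == g2[0]:
        raise DegenerateDataError(f"{variable} is constant in both groups")
    test = choose_test(g1, g2)
    if test == STUDENT_T:
        stat, p = sps.ttest_ind(g1, g2, equal_var=equal_var)
    else:
        stat, p = sps.mannwhitneyu(g1, g2, alternative="two-sided")
    summaries = {str(groups[0]): _summary(g1, test), str(groups[1]): _summary(g2, test)}
    return ComparisonResult(variable, test, float(stat), float(p), summaries)


def correlate_with_los(
    df: pd.DataFrame, variable: str, los_col: str = "los_icu_days"
) -> Tuple[float, float]:
    """Pearson correlation (r, two-sided p) of a variable with LOS-ICU."""
    sub = df[[variable, los_col]].dropna()
    if len(sub) < 3:
        raise DegenerateDataError(
            f"need >= 3 complete pairs for correlation, got {len(sub)}")
    x = sub[variable].to_numpy(dtype=float)
    y = sub[los_col].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError(f"zero variance in {variable} or {los_col}")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def los_regression(
    df: pd.DataFrame,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    outcome: str = "los_icu_days",
    scale_ph_by_100: bool = True,
) -> RegressionResult:
    """OLS of LOS-ICU on the predictor battery, with intercept.

    Reports per-predictor coefficient, 95% CI and p-value, plus R² and the
    Durbin–Watson statistic of the residuals.  Rank deficiency raises
    :class:`CollinearityError` naming the dependent columns.
    """
    cols = list(predictors) + [outcome]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DomainError(f"unknown columns: {missing}")
    sub = df[cols].dropna().astype(float)
    n = len(sub)
    if n <= len(predictors) + 1:
        raise DegenerateDataError(
            f"n={n} too small for {len(predictors)} predictors")
    X = sub[list(predictors)].copy()
    if scale_ph_by_100 and "delta_ph" in X.columns:
        X["delta_ph"] = X["delta_ph"] * 100.0
    y = sub[outcome]
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # Identify dependent columns from the QR decomposition's R diagonal.
        _, r = np.linalg.qr(Xc.to_numpy())
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(Xc.shape) * np.finfo(float).eps
        bad = [Xc.columns[i] for i in np.where(diag <= tol)[0]]
        raise CollinearityError(bad or list(Xc.columns))
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "coef": fit.params,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p_value": fit.pvalues,
    })
    return RegressionResult(
        outcome=outcome,
        table=table,
        r_squared=float(fit.rsquared),
        durbin_watson=float(durbin_watson(fit.resid)),
        n=n,
    )


def two_sample_t_power(
    n1: int, n2: int, mean_diff: float, sd: float, alpha: float = 0.05
) -> float:
    """Power of the two-sided unpaired t-test via the noncentral t.

    The noncentrality parameter is ``(mean_diff/sd) * sqrt(n1*n2/(n1+n2))``
    with ``n1 + n2 - 2`` degrees of freedom.  At ``mean_diff=0`` the power
    equals ``alpha`` exactly.
    """
    if n1 < 2 or n2 < 2:
        raise DomainError("need n >= 2 per group")
    if not sd > 0:
        raise DomainError(f"sd must be positive, got {sd}")
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0,1), got {alpha}")
    dof = n1 + n2 - 2
    nc = (mean_diff / sd) * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1 - alpha / 2, dof)
    power = sps.nct.sf(tcrit, dof, nc) + sps.nct.cdf(-tcrit, dof, nc)
    return float(power)
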