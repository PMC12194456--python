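"""Statistical battery against exhaustive-enumeration and simulation oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dkabase import (
    choose_test,
    compare_groups,
    correlate_with_los,
    los_regression,
    two_sample_t_power,
)
from dkabase.errors import CollinearityError, DegenerateDataError, DomainError
from dkabase.stats import MANN_WHITNEY, STUDENT_T, choose_categorical_test


def mann_whitney_exact_oracle(x, y):
    """Two-sided exact Mann–Whitney p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def fisher_exact_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration of the 2x2 margin."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = sps.hypergeom.pmf(a, n, col1, row1)
    p = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = sps.hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return min(p, 1.0)


class TestChooseTest:
    def test_normal_quantile_samples_get_t(self):
        # exact normal quantiles are as Gaussian as a sample can be
        q = sps.norm.ppf(np.linspace(0.05, 0.95, 15))
        assert choose_test(q, q + 1.0) == STUDENT_T

    def test_heavy_tailed_sample_gets_mann_whitney(self):
        g1 = np.linspace(0, 1, 12)
        g2 = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 50.0, 100.0, 400.0])
        assert sps.shapiro(g2).pvalue < 0.05  # construction check
        assert choose_test(g1, g2) == MANN_WHITNEY

    def test_insufficient_n(self):
        with pytest.raises(DegenerateDataError):
            choose_test([1, 2], [1, 2, 3])

    def test_expected_count_below_5_gets_fisher(self):
        assert choose_categorical_test([[1, 9], [8, 2]]) == "fisher_exact"
        assert choose_categorical_test([[20, 30], [25, 25]]) == "chi_square"


class TestCompareGroups:
    @staticmethod
    def _df(g1, g2):
        return pd.DataFrame({
            "group_label": ["GI"] * len(g1) + ["GII"] * len(g2),
            "x": list(g1) + list(g2),
        })

    def test_identical_groups_p_one(self):
        res = compare_groups(self._df([1, 2, 3, 4], [1, 2, 3, 4]), "x")
        assert res.p_value == pytest.approx(1.0)
        # and the rank test itself is symmetric under full ties
        _, p = sps.mannwhitneyu([1, 2, 3, 4], [1, 2, 3, 4],
                                alternative="two-sided")
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        res = compare_groups(self._df([1, 2, 3], [101, 102, 103]), "x")
        assert res.p_value < 0.05

    def test_constant_in_both_groups_degenerate(self):
        with pytest.raises(DegenerateDataError):
            compare_groups(self._df([5, 5, 5], [5, 5, 5]), "x")

    def test_single_group_degenerate(self):
        df = pd.DataFrame({"group_label": ["GI"] * 6, "x": range(6)})
        with pytest.raises(DegenerateDataError):
            compare_groups(df, "x")

    @pytest.mark.parametrize("n1, n2, seed", [
        (3, 3, 0), (4, 5, 1), (6, 6, 2), (2, 6, 3), (5, 3, 4),
    ])
    def test_mann_whitney_matches_exact_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        # continuous draws: no ties, so scipy uses the exact distribution
        x = rng.normal(size=n1)
        y = rng.normal(loc=0.8, size=n2)
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        assert p == pytest.approx(mann_whitney_exact_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("table", [
        [[1, 9], [11, 3]], [[2, 3], [4, 5]], [[0, 5], [6, 1]], [[7, 2], [2, 7]],
    ])
    def test_fisher_matches_hypergeometric_enumeration(self, table):
        _, p = sps.fisher_exact(table)
        assert p == pytest.approx(fisher_exact_oracle(table), abs=1e-9)


class TestCorrelateWithLos:
    def test_perfect_positive(self):
        df = pd.DataFrame({"v": [1, 2, 3, 4], "los_icu_days": [2, 4, 6, 8]})
        r, p = correlate_with_los(df, "v")
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        df = pd.DataFrame({"v": [1, 2, 3, 4], "los_icu_days": [9, 8, 7, 6]})
        r, _ = correlate_with_los(df, "v")
        assert r == pytest.approx(-1.0)

    def test_zero_variance_degenerate(self):
        df = pd.DataFrame({"v": [1, 1, 1], "los_icu_days": [2, 3, 4]})
        with pytest.raises(DegenerateDataError):
            correlate_with_los(df, "v")


def _synthetic_regression_frame(n, seed, beta_cl=0.2, noise_sd=0.1):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        c: rng.normal(size=n)
        for c in ("age", "bmi", "apache2", "sofa", "delta_ph", "delta_paco2",
                  "delta_hco3", "delta_na", "delta_lactate", "delta_sig",
                  "delta_glucose")
    })
    df["delta_cl"] = rng.normal(scale=3.0, size=n)
    df["los_icu_days"] = 2 + beta_cl * df["delta_cl"] + rng.normal(
        scale=noise_sd, size=n)
    return df


class TestLosRegression:
    def test_parameter_recovery(self):
        df = _synthetic_regression_frame(200, seed=5)
        res = los_regression(df)
        assert 0.15 <= res.table.loc["delta_cl", "coef"] <= 0.25
        ci = res.table.loc["delta_cl", ["ci_low", "ci_high"]]
        assert ci["ci_low"] <= 0.2 <= ci["ci_high"]

    def test_noise_free_r_squared_one(self):
        df = _synthetic_regression_frame(100, seed=6, noise_sd=1e-12)
        res = los_regression(df)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_collinearity_error_names_columns(self):
        df = _synthetic_regression_frame(100, seed=7)
        df["delta_na"] = 2 * df["delta_cl"] + 1
        with pytest.raises(CollinearityError):
            los_regression(df)

    def test_type_one_error_rate_near_nominal(self):
        # pure-noise outcome: pooled per-predictor rejection rate ~5%
        rng = np.random.default_rng(8)
        rejections = total = 0
        for rep in range(150):
            df = _synthetic_regression_frame(200, seed=1000 + rep, beta_cl=0.0,
                                             noise_sd=1.0)
            res = los_regression(df)
            pvals = res.table["p_value"].drop("const")
            rejections += (pvals < 0.05).sum()
            total += len(pvals)
        rate = rejections / total
        assert 0.03 < rate < 0.075

    def test_n_too_small(self):
        df = _synthetic_regression_frame(10, seed=9)
        with pytest.raises(DegenerateDataError):
            los_regression(df)


class TestPower:
    def test_study_configuration_reaches_099(self):
        # 21 vs 13 patients, 9 mmol/L difference, 3 mmol/L sd, alpha 0.05
        assert two_sample_t_power(21, 13, 9, 3, 0.05) >= 0.99

    def test_null_effect_power_equals_alpha(self):
        assert two_sample_t_power(10, 10, 0, 1, 0.05) == pytest.approx(0.05)
        assert two_sample_t_power(10, 10, 0, 1, 0.10) == pytest.approx(0.10)

    def test_monotone_in_effect_and_n(self):
        p_small = two_sample_t_power(10, 10, 0.5, 1)
        assert two_sample_t_power(10, 10, 1.0, 1) > p_small
        assert two_sample_t_power(50, 50, 0.5, 1) > p_small
        assert two_sample_t_power(10, 10, 0.5, 1, alpha=0.10) > p_small

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            two_sample_t_power(1, 10, 1, 1)
        with pytest.raises(DomainError):
            two_sample_t_power(10, 10, 1, 0)
        with pytest.raises(DomainError):
            two_sample_t_power(10, 10, 1, 1, alpha=1.5)
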