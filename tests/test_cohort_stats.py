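"""cohort_stats: odds ratios, exclusion, prevalence, proportion tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from paralocus.cohort_stats import (
    CohortTable,
    UndefinedOddsRatioError,
    exclude_carriers,
    format_prevalence,
    odds_ratio,
    odds_ratio_from_counts,
    prevalence,
    proportion_test,
)


# ---------------------------------------------------------------------------
# odds ratio against an independent logistic-regression oracle
# ---------------------------------------------------------------------------


def _logit_or(a, b, c, d):
    # [DERIVED] statsmodels logistic regression on the expanded 2x2
    import statsmodels.api as sm

    y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return math.exp(fit.params[1])


def test_or_equals_logistic_mle_random_tables():
    rng = np.random.default_rng(99)
    for _ in range(25):  # 100 tables in the acceptance suite; 25 here for speed
        a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
        res = odds_ratio_from_counts(a, b, c, d)
        assert abs(res.or_value - _logit_or(a, b, c, d)) / res.or_value < 1e-6


def test_or_symmetry_and_ci():
    res = odds_ratio_from_counts(50, 50, 50, 50)
    assert res.or_value == 1.0
    assert res.ci_low < 1.0 < res.ci_high
    # [DERIVED] hand-computed Wald CI for (171, 2026, 43, 1054)
    res = odds_ratio_from_counts(171, 2026, 43, 1054)
    se = math.sqrt(1 / 171 + 1 / 2026 + 1 / 43 + 1 / 1054)
    assert abs(res.ci_low - res.or_value * math.exp(-1.959963984540054 * se)) < 1e-12


def test_or_haldane_correction_flagged():
    res = odds_ratio_from_counts(0, 50, 10, 40)
    assert res.continuity_corrected
    assert res.or_value == (0.5 * 40.5) / (50.5 * 10.5)


def test_or_structural_zero_margin_raises():
    with pytest.raises(UndefinedOddsRatioError):
        odds_ratio_from_counts(0, 0, 10, 40)
    with pytest.raises(UndefinedOddsRatioError):
        odds_ratio_from_counts(0, 10, 0, 40)


def test_published_cohort_ors():
    # [PUBLISHED] odds ratios 2.07 (PD) and 3.68 (LBD); 2.12 printed for severe
    assert round(odds_ratio_from_counts(171, 2026, 43, 1054).or_value, 2) == 2.07
    assert round(odds_ratio_from_counts(298, 2241, 67, 1855).or_value, 2) == 3.68
    # printed 2.12; the cross-product gives 2.128 (agrees at +-0.01)
    assert abs(odds_ratio_from_counts(38, 2159, 9, 1088).or_value - 2.12) <= 0.01


# ---------------------------------------------------------------------------
# table operations
# ---------------------------------------------------------------------------


def _table():
    return CohortTable.from_counts(
        "any_variant", 171, 2197, 43, 1097,
        extra_flags={"p.N409S": (30, 20)},
    )


def test_from_counts_and_counts():
    t = _table()
    assert t.counts("any_variant") == (171, 2026, 43, 1054)
    assert set(t.flag_columns) == {"any_variant", "p.N409S"}


def test_exclude_carriers_removes_from_both_cohorts():
    # [PUBLISHED] excluding p.N409S carriers leaves denominators 2197 and 1097
    t = CohortTable.from_counts("p.N409S", 128, 2325, 158, 1255)
    t2 = exclude_carriers(t, "p.N409S")
    case = t2.data[t2.data["cohort"] == "case"]
    ctrl = t2.data[t2.data["cohort"] == "control"]
    assert (len(case), len(ctrl)) == (2197, 1097)
    assert any("128 case, 158 control" in line for line in t2.exclusion_log)


def test_exclude_identity_when_no_carriers():
    t = CohortTable.from_counts("flag", 0, 10, 0, 10)
    assert len(exclude_carriers(t, "flag").data) == 20


def test_exclude_all_warns():
    t = CohortTable.from_counts("flag", 5, 5, 5, 5)
    t2 = exclude_carriers(t, "flag")
    assert t2.data.empty
    assert any("all samples excluded" in line for line in t2.exclusion_log)


def test_table_validation():
    import pandas as pd

    with pytest.raises(ValueError):
        CohortTable(pd.DataFrame({"sample_id": ["a"], "cohort": ["weird"]}))
    with pytest.raises(ValueError):
        CohortTable(pd.DataFrame({"sample_id": ["a", "a"], "cohort": ["case", "case"]}))


def test_table_tsv_round_trip(tmp_path):
    t = _table()
    t2 = CohortTable.from_tsv(t.to_tsv(tmp_path / "t.tsv"))
    assert t2.counts("any_variant") == t.counts("any_variant")
    assert t2.counts("p.N409S") == t.counts("p.N409S")


# ---------------------------------------------------------------------------
# prevalence and proportion tests
# ---------------------------------------------------------------------------


def test_prevalence_and_formatting():
    t = _table()
    assert format_prevalence(prevalence(t, "any_variant", "case")) == "7.8"
    assert format_prevalence(prevalence(t, "any_variant", "control")) == "3.9"
    assert format_prevalence(100 * 71 / 10407) == "0.68"
    assert format_prevalence(0.0) == "0.00"


def test_prevalence_complement_sums_to_100():
    t = _table()
    p = prevalence(t, "any_variant", "case")
    non = 100.0 * (2197 - 171) / 2197
    assert p + non == 100.0


def test_proportion_test_identical_is_one():
    assert proportion_test(5, 50, 5, 50) == 1.0


def test_proportion_fisher_matches_scipy_and_hypergeom():
    # [DERIVED] direct hypergeometric enumeration of the two-sided p-value
    a, n1, b, n2 = 7, 146, 71, 10407
    p = proportion_test(a, n1, b, n2)
    table = [[a, n1 - a], [b, n2 - b]]
    assert p == stats.fisher_exact(table)[1]
    M, K, N = n1 + n2, a + b, n1
    probs = [stats.hypergeom.pmf(k, M, K, N) for k in range(K + 1)]
    p_obs = stats.hypergeom.pmf(a, M, K, N)
    p_manual = sum(q for q in probs if q <= p_obs * (1 + 1e-9))
    assert abs(p - p_manual) < 1e-9


def test_proportion_zero_cell_finite():
    p = proportion_test(0, 1000, 50, 1000)
    assert 0 < p < 1


def test_proportion_chi2_option():
    p = proportion_test(30, 100, 10, 100, method="chi2")
    assert p == stats.chi2_contingency([[30, 70], [10, 90]], correction=True)[1]
    with pytest.raises(ValueError):
        proportion_test(1, 10, 1, 10, method="bogus")
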