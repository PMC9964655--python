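"""Additive ANOVA, Duncan's multiple range test, homoscedasticity check."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from emgrehab import (
    check_homoscedasticity,
    duncan_mrt,
    fit_additive_anova,
    validate_results_table,
)
from emgrehab.stats import AnovaTable
from oracles import sequential_ss_oracle

TESTS = ["A", "B", "C", "D"]


def _balanced_table(rng, n_subjects=18, effects=None, sd=0.5):
    """Balanced cohort table with random per-subject order permutations."""
    effects = effects or {t: 0.0 for t in TESTS}
    rows = []
    for s in range(1, n_subjects + 1):
        subj_eff = rng.normal(0, 0.5)
        order = rng.permutation(TESTS)
        for pos, t in enumerate(order, start=1):
            rows.append(
                {
                    "subject": s,
                    "test": t,
                    "order": pos,
                    "d_l2": 3.0 + effects[t] + subj_eff + rng.normal(0, sd),
                }
            )
    return pd.DataFrame(rows)


def test_anova_df_bookkeeping_for_default_cohort():
    """18 subjects x 4 tests: df = 3 (test), 3 (order), 17 (individual), 48 residual."""
    rng = np.random.default_rng(0)
    aov = fit_additive_anova(_balanced_table(rng))
    assert int(aov.table.loc["Test", "df"]) == 3
    assert int(aov.table.loc["Order", "df"]) == 3
    assert int(aov.table.loc["Individual", "df"]) == 17
    assert aov.residual_df == 48
    assert int(aov.table["df"].sum()) == 71


def test_anova_ss_decomposition_conserves_total():
    rng = np.random.default_rng(1)
    table = _balanced_table(rng)
    aov = fit_additive_anova(table)
    total = np.sum((table["d_l2"] - table["d_l2"].mean()) ** 2)
    assert aov.table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)


def test_anova_matches_projection_oracle_on_small_tables():
    """Sequential SS from explicit nested least-squares fits matches the
    implementation on random small balanced tables."""
    rng = np.random.default_rng(2)
    for _ in range(10):
        table = _balanced_table(rng, n_subjects=6)
        aov = fit_additive_anova(table)
        oracle = sequential_ss_oracle(table)
        for factor in ("Test", "Order", "Individual", "Residuals"):
            assert aov.table.loc[factor, "sum_sq"] == pytest.approx(
                oracle[factor], rel=1e-9, abs=1e-12
            )


def test_anova_rejects_saturated_model():
    rng = np.random.default_rng(3)
    table = _balanced_table(rng, n_subjects=2)
    with pytest.raises(ValueError, match="saturated"):
        fit_additive_anova(table)


def test_anova_rejects_confounded_order():
    """Every subject taking the tests in the same order confounds order with test."""
    rng = np.random.default_rng(4)
    rows = []
    for s in range(1, 19):
        for pos, t in enumerate(TESTS, start=1):
            rows.append(
                {"subject": s, "test": t, "order": pos, "d_l2": rng.normal(3, 1)}
            )
    with pytest.raises(ValueError, match="confounded"):
        fit_additive_anova(pd.DataFrame(rows))


def test_unbalanced_table_rejected():
    rng = np.random.default_rng(5)
    table = _balanced_table(rng).iloc[:-1]
    with pytest.raises(ValueError, match="unbalanced"):
        validate_results_table(table)


def test_duncan_identical_means_all_p_one():
    rng = np.random.default_rng(6)
    base = rng.normal(3, 0.5, 18)
    rows = []
    for s in range(1, 19):
        order = rng.permutation(TESTS)
        for pos, t in enumerate(order, start=1):
            rows.append({"subject": s, "test": t, "order": pos, "d_l2": base[s - 1]})
    table = pd.DataFrame(rows)
    aov = fit_additive_anova(table)
    res = duncan_mrt(table, aov)
    offdiag = res.p_values.values[~np.eye(4, dtype=bool)]
    assert np.allclose(offdiag, 1.0)


def test_duncan_two_groups_equals_pooled_t_test():
    """With two groups the r = 2 range criterion is the pooled t-test."""
    rng = np.random.default_rng(7)
    rows = []
    for s in range(1, 13):
        subj = rng.normal(0, 0.3)
        for pos, (t, eff) in enumerate([("A", 0.0), ("B", 0.6)], start=1):
            rows.append(
                {
                    "subject": s,
                    "test": t,
                    "order": pos if s % 2 else 3 - pos,
                    "d_l2": 3.0 + eff + subj + rng.normal(0, 0.5),
                }
            )
    table = pd.DataFrame(rows)
    aov = fit_additive_anova(table)
    res = duncan_mrt(table, aov)
    means = table.groupby("test")["d_l2"].mean()
    n = 12
    t_stat = abs(means["A"] - means["B"]) / np.sqrt(aov.residual_ms * 2 / n)
    p_t = 2 * spstats.t.sf(t_stat, aov.residual_df)
    assert res.pair_p("A", "B") == pytest.approx(p_t, abs=1e-6)


def test_duncan_p_monotone_in_mean_separation():
    """Widening the mean difference at fixed residual MS never raises p."""
    aov = AnovaTable(
        pd.DataFrame(
            {
                "df": [3, 3, 17, 48],
                "sum_sq": [1.0, 1.0, 1.0, 48 * 0.28],
                "mean_sq": [1 / 3, 1 / 3, 1 / 17, 0.28],
                "f_value": [np.nan] * 4,
                "p_value": [np.nan] * 4,
            },
            index=["Test", "Order", "Individual", "Residuals"],
        )
    )
    rng = np.random.default_rng(8)
    last_p = 1.1
    for delta in [0.0, 0.2, 0.4, 0.8, 1.6]:
        rows = []
        for s in range(1, 19):
            order = rng.permutation(TESTS)
            for pos, t in enumerate(order, start=1):
                mean = 3.0 + (delta if t == "A" else 0.0)
                rows.append({"subject": s, "test": t, "order": pos, "d_l2": mean})
        table = pd.DataFrame(rows)
        res = duncan_mrt(table, aov)
        p = res.pair_p("A", "B")
        assert p <= last_p + 1e-12
        last_p = p


def test_duncan_requires_two_groups():
    rows = [
        {"subject": s, "test": "A", "order": 1, "d_l2": float(s)} for s in range(1, 5)
    ]
    aov = AnovaTable(
        pd.DataFrame(
            {"df": [1, 1, 1, 1], "sum_sq": [1.0] * 4, "mean_sq": [1.0] * 4,
             "f_value": [np.nan] * 4, "p_value": [np.nan] * 4},
            index=["Test", "Order", "Individual", "Residuals"],
        )
    )
    with pytest.raises(ValueError, match="two groups"):
        duncan_mrt(pd.DataFrame(rows), aov)


def test_levene_null_pass_rate_near_95_percent():
    """Homogeneous groups pass Levene at alpha = 0.05 about 95% of the time."""
    rng = np.random.default_rng(9)
    passes = 0
    n_rep = 200
    for _ in range(n_rep):
        table = _balanced_table(rng, n_subjects=18)
        passes += check_homoscedasticity(table).passed
    assert 0.90 <= passes / n_rep <= 0.99


def test_levene_detects_inflated_variance():
    """One group with 10x the spread fails the check for most seeds."""
    rng = np.random.default_rng(10)
    fails = 0
    n_rep = 50
    for _ in range(n_rep):
        table = _balanced_table(rng, n_subjects=18, sd=0.3)
        mask = table["test"] == "D"
        noise = rng.normal(0, 3.0, mask.sum())
        table.loc[mask, "d_l2"] += noise
        fails += not check_homoscedasticity(table).passed
    assert fails / n_rep > 0.8


def test_levene_zero_variance_degenerate_case_warns():
    rows = []
    for s in range(1, 19):
        for pos, t in enumerate(TESTS, start=1):
            rows.append({"subject": s, "test": t, "order": pos, "d_l2": 2.0})
    with pytest.warns(UserWarning, match="zero variance"):
        res = check_homoscedasticity(pd.DataFrame(rows))
    assert res.passed


def test_bartlett_available_behind_flag():
    rng = np.random.default_rng(11)
    res = check_homoscedasticity(_balanced_table(rng), method="bartlett")
    assert res.method == "bartlett" and 0 <= res.p_value <= 1
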