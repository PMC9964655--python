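"""Inference on trial scores: additive ANOVA, Duncan's MRT, homoscedasticity.

The cohort produces a balanced long-format table — one L2 score per
subject x test, with the within-subject presentation order recorded — and
the questions are (i) does the feedback condition affect performance, and
(ii) which conditions differ pairwise.

The additive model is ``d_l2 ~ test + order + individual`` with no
interactions; the individual enters purely to block between-subject
variability.  Sums of squares are sequential (Type I) in that order; for a
balanced design sequential and marginal decompositions coincide.  Pairwise
comparisons use Duncan's multiple range test: after sorting the group
means, two groups separated by r ranks differ at level alpha when their
mean difference exceeds

    q_{1-alpha_p}(r, df_resid) * sqrt(MS_resid / n_per_group),

where the protection level is alpha_p = 1 - (1 - alpha)^(r - 1).  The
reported pairwise p-value is the smallest alpha at which the pair
separates, obtained by inverting that criterion in closed form:
alpha = 1 - (1 - P(Q_{r,df} > q_obs))^(1/(r-1)).  For r = 2 this reduces
to the pooled-variance two-sample t-test p-value.

Variance homogeneity across the four test groups is checked with Levene's
test (median-centered, robust); Bartlett's test is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

RESULTS_COLUMNS = ("subject", "test", "order", "d_l2")


def validate_results_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format score table: columns present, design balanced."""
    missing_cols = set(RESULTS_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"results table is missing columns {sorted(missing_cols)}")
    tests = sorted(table["test"].unique())
    subjects = sorted(table["subject"].unique())
    counts = table.groupby(["subject", "test"], observed=True).size()
    for s in subjects:
        for t in tests:
            c = counts.get((s, t), 0)
            if c != 1:
                raise ValueError(
                    f"unbalanced design: subject {s}, test {t} has {c} rows "
                    "(expected exactly 1)"
                )
    if not np.isfinite(table["d_l2"]).all():
        raise ValueError("d_l2 contains non-finite values")
    return table


@dataclass
class AnovaTable:
    """Sequential ANOVA decomposition, rows Test / Order / Individual / Residuals."""

    table: pd.DataFrame  # index: factor; columns: df, sum_sq, mean_sq, f_value, p_value

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["Residuals", "df"])

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["Residuals", "mean_sq"])

    def p_value(self, factor: str) -> float:
        return float(self.table.loc[factor, "p_value"])


def fit_additive_anova(table: pd.DataFrame) -> AnovaTable:
    """Sequential (Type I) ANOVA of d_l2 on test, order and individual.

    With the default 18-subject x 4-test cohort the decomposition has
    df 3 (test), 3 (order), 17 (individual) and 48 residual.
    """
    table = validate_results_table(table)
    n = len(table)
    n_tests = table["test"].nunique()
    n_orders = table["order"].nunique()
    n_subjects = table["subject"].nunique()
    resid_df = n - 1 - (n_tests - 1) - (n_orders - 1) - (n_subjects - 1)
    if resid_df <= 0:
        raise ValueError(
            f"saturated model: {n} rows leave {resid_df} residual df; "
            "need more subjects or fewer factors"
        )
    model = smf.ols(
        "d_l2 ~ C(test) + C(order) + C(subject)", data=table.astype({"subject": str})
    ).fit()
    expected_rank = 1 + (n_tests - 1) + (n_orders - 1) + (n_subjects - 1)
    if model.df_model + 1 < expected_rank:
        raise ValueError(
            "rank-deficient design: a factor is confounded (e.g. order "
            "perfectly aligned with test); re-randomize the test order"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance inputs
        aov = anova_lm(model, typ=1)
    out = pd.DataFrame(
        {
            "df": aov["df"].astype(int).values,
            "sum_sq": aov["sum_sq"].values,
            "mean_sq": (aov["sum_sq"] / aov["df"]).values,
            "f_value": aov["F"].values,
            "p_value": aov["PR(>F)"].values,
        },
        index=["Test", "Order", "Individual", "Residuals"],
    )
    return AnovaTable(out)


@dataclass
class DuncanResult:
    """Duncan's multiple-range pairwise comparisons over the test groups."""

    group_means: pd.Series          # mean d_l2 per test, index sorted by name
    p_values: pd.DataFrame          # symmetric matrix of pairwise p-values
    alpha: float

    def significant(self) -> pd.DataFrame:
        return self.p_values < self.alpha

    def pair_p(self, a: str, b: str) -> float:
        return float(self.p_values.loc[a, b])


def duncan_mrt(
    table: pd.DataFrame, anova: AnovaTable, alpha: float = 0.05
) -> DuncanResult:
    """Duncan's multiple range test on the test-group means.

    Uses the ANOVA residual mean square and df as the pooled error.  The
    pairwise p-value is the smallest alpha at which the pair's mean
    difference exceeds the least significant range for its rank span.
    """
    table = validate_results_table(table)
    groups = sorted(table["test"].unique())
    if len(groups) < 2:
        raise ValueError("Duncan's test needs at least two groups")
    sizes = table.groupby("test", observed=True).size()
    if sizes.nunique() != 1:
        raise ValueError("Duncan's test requires equal group sizes")
    n_per_group = int(sizes.iloc[0])
    means = table.groupby("test", observed=True)["d_l2"].mean()
    se = np.sqrt(anova.residual_ms / n_per_group)
    order = means.sort_values().index.to_list()  # ascending rank positions
    pos = {g: i for i, g in enumerate(order)}
    p = pd.DataFrame(np.ones((len(groups), len(groups))), index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            r = abs(pos[a] - pos[b]) + 1
            if se == 0:
                pv = 1.0 if means[a] == means[b] else 0.0
            else:
                q_obs = abs(means[a] - means[b]) / se
                alpha_p = float(
                    spstats.studentized_range.sf(q_obs, r, anova.residual_df)
                )
                pv = 1.0 - (1.0 - alpha_p) ** (1.0 / (r - 1))
            p.loc[a, b] = p.loc[b, a] = pv
    return DuncanResult(group_means=means, p_values=p, alpha=alpha)


@dataclass
class HomoscedasticityResult:
    statistic: float
    p_value: float
    passed: bool
    method: str


def check_homoscedasticity(
    table: pd.DataFrame, alpha: float = 0.05, method: str = "levene"
) -> HomoscedasticityResult:
    """Equality-of-variance check of d_l2 across the test groups."""
    table = validate_results_table(table)
    samples = [g["d_l2"].to_numpy() for _, g in table.groupby("test", observed=True)]
    for g in samples:
        if len(g) < 2:
            raise ValueError("each test group needs at least 2 observations")
    if all(np.ptp(g) == 0 for g in samples):
        warnings.warn(
            "all groups have zero variance; homoscedasticity is trivially "
            "satisfied but the test statistic is undefined",
            stacklevel=2,
        )
        return HomoscedasticityResult(np.nan, np.nan, True, method)
    if method == "levene":
        stat, pv = spstats.levene(*samples, center="median")
    elif method == "bartlett":
        stat, pv = spstats.bartlett(*samples)
    else:
        raise ValueError(f"unknown method {method!r}; use 'levene' or 'bartlett'")
    return HomoscedasticityResult(float(stat), float(pv), bool(pv > alpha), method)


def plot_l2_by_test(table: pd.DataFrame, path: str) -> None:
    """Boxplot of d_l2 by test condition (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = validate_results_table(table)
    groups = sorted(table["test"].unique())
    data = [table.loc[table["test"] == g, "d_l2"] for g in groups]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=groups)
    ax.set_xlabel("Test")
    ax.set_ylabel(r"$d_{L2}$ (gesture$^2\cdot$s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
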