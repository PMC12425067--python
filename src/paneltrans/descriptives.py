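"""Baseline group comparisons (Table-1-style descriptive statistics).

Categorical variables are compared across groups with Pearson's chi-square
test (no continuity correction); continuous variables with Welch's t or the
Wilcoxon rank-sum test for two groups, and one-way ANOVA or Kruskal–Wallis
for more than two.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pearson_chi_square", "group_compare_continuous", "table_one"]


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an R×C count table.

    Returns ``(statistic, df, p)``.  Expected counts come from the product of
    margins; no Yates correction is applied.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins: a row or column sums to zero")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def group_compare_continuous(values, groups, method: str = "auto") -> tuple[float, float]:
    """Compare a continuous variable between groups.

    ``method``: ``anova``, ``kruskal_wallis``, ``t`` (Welch) or ``wilcoxon``
    (rank sum); ``auto`` picks Welch's t for 2 groups, ANOVA otherwise.
    Constant data under a rank test returns (0, 1) rather than erroring.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")

    if method == "auto":
        method = "t" if len(labels) == 2 else "anova"
    if method in ("t", "wilcoxon") and len(labels) != 2:
        raise ValueError(f"{method!r} requires exactly 2 groups")

    if method == "anova":
        res = stats.f_oneway(*samples)
    elif method == "kruskal_wallis":
        if np.ptp(values) == 0:
            return 0.0, 1.0
        res = stats.kruskal(*samples)
    elif method == "t":
        res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
    elif method == "wilcoxon":
        if np.ptp(values) == 0:
            return 0.0, 1.0
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided",
                                 method="asymptotic")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


# Table-1 variable lists (baseline wave, after scoring)
_BINARY_VARS = ["sex_male", "married", "edu_high", "live_others", "alcohol", "smoke",
                "vig_act", "dm", "cancer", "heart", "stroke", "htn", "lung", "arthritis"]
_CONTINUOUS_VARS = ["age", "cesd_total", "jss_total", "tics_total"]


def table_one(baseline: pd.DataFrame, group_col: str,
              continuous_method: str = "kruskal_wallis") -> pd.DataFrame:
    """Descriptive comparison of baseline characteristics across groups.

    ``baseline`` is one row per participant with encoded covariates (see
    :func:`paneltrans.cohort.collapse_to_subject`).  Binary variables get
    per-group counts/percentages and a chi-square test; continuous variables
    get means/SDs and the chosen k-sample test.
    """
    groups = pd.unique(baseline[group_col])
    rows = []
    for var in _BINARY_VARS:
        if var not in baseline.columns:
            continue
        tab = pd.crosstab(baseline[var].astype(float) > 0, baseline[group_col])
        if tab.shape[0] < 2:
            continue
        stat, df, p = pearson_chi_square(tab.to_numpy())
        row = {"variable": var, "type": "binary", "statistic": stat, "df": df, "p": p}
        for g in groups:
            sub = baseline[baseline[group_col] == g]
            row[f"{g}_n"] = int((sub[var].astype(float) > 0).sum())
            row[f"{g}_pct"] = 100.0 * (sub[var].astype(float) > 0).mean()
        rows.append(row)
    for var in _CONTINUOUS_VARS:
        if var not in baseline.columns:
            continue
        method = continuous_method if len(groups) > 2 else "wilcoxon"
        stat, p = group_compare_continuous(
            baseline[var].to_numpy(dtype=float), baseline[group_col].to_numpy(), method)
        row = {"variable": var, "type": "continuous", "statistic": stat,
               "df": np.nan, "p": p}
        for g in groups:
            sub = baseline.loc[baseline[group_col] == g, var].astype(float)
            row[f"{g}_mean"] = sub.mean()
            row[f"{g}_sd"] = sub.std()
        rows.append(row)
    return pd.DataFrame(rows)
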