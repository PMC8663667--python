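"""Descriptive and bivariate statistics for rural-vs-urban comparisons.

Continuous variables are compared with two-tailed pooled-variance t tests
(Welch behind a flag), categorical variables with the Pearson chi-square
test without continuity correction (Yates behind a flag), and pairwise
associations with Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

INCOME_SPLIT_USD = 35_000  # median split for the income covariate


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_labels: tuple
    group_n: tuple
    group_stats: tuple  # (mean, sd) per group, or (count, percent) per group
    statistic: float
    p_value: float
    test_name: str


def two_sample_t(values_a, values_b, labels=("a", "b"), variable="", welch=False) -> GroupComparison:
    """Two-tailed two-sample t test; pooled variance by default."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    for name, v in zip(labels, (a, b)):
        if len(v) < 2:
            raise ValidationError(f"group {name}: needs n >= 2")
        if np.var(v, ddof=1) == 0:
            raise ValidationError(f"group {name}: zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        variable=variable,
        group_labels=tuple(labels),
        group_n=(len(a), len(b)),
        group_stats=(
            (float(a.mean()), float(a.std(ddof=1))),
            (float(b.mean()), float(b.std(ddof=1))),
        ),
        statistic=float(t),
        p_value=float(p),
        test_name="welch_t" if welch else "pooled_t",
    )


def chi_square_2x2(a: int, b: int, c: int, d: int, labels=("a", "b"), variable="", yates=False) -> GroupComparison:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df = 1.

    Rows are groups, columns outcome yes/no.  No continuity correction by
    default.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValidationError("counts: must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("counts: all margins must be > 0")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    n1, n2 = a + b, c + d
    return GroupComparison(
        variable=variable,
        group_labels=tuple(labels),
        group_n=(int(n1), int(n2)),
        group_stats=((int(a), 100.0 * a / n1), (int(c), 100.0 * c / n2)),
        statistic=float(chi2),
        p_value=float(p),
        test_name="chi_square_yates" if yates else "chi_square",
    )


def pearson_correlation(x, y) -> tuple:
    """Pearson r with two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("correlation: needs paired samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("correlation: undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


DEFAULT_TABLE_VARIABLES = (
    ("income_band", "categorical"),  # share below the $35k split
    ("age", "continuous"),
    ("visits", "continuous"),
)


def table2_summary(
    patients: pd.DataFrame,
    group_col: str = "rurality_code",
    group_labels: tuple = ("rural", "urban"),
    variables=DEFAULT_TABLE_VARIABLES,
    welch: bool = False,
    yates: bool = False,
) -> pd.DataFrame:
    """Respondent-characteristics table: one row per configured variable.

    Categorical variables (0/1) are compared by chi-square on the count of
    the low category; continuous variables by t test.  ``group_col`` must
    be the 0/1 moderator (0 = first label).
    """
    g0 = patients[patients[group_col] == 0]
    g1 = patients[patients[group_col] == 1]
    rows = []
    for var, kind in variables:
        if kind == "categorical":
            a = int((g0[var] == 0).sum())  # low category count per group
            b = int((g0[var] == 1).sum())
            c = int((g1[var] == 0).sum())
            d = int((g1[var] == 1).sum())
            cmp = chi_square_2x2(a, b, c, d, labels=group_labels, variable=var, yates=yates)
            summary0 = f"{cmp.group_stats[0][0]} ({cmp.group_stats[0][1]:.0f}%)"
            summary1 = f"{cmp.group_stats[1][0]} ({cmp.group_stats[1][1]:.0f}%)"
        else:
            cmp = two_sample_t(
                g0[var].dropna(), g1[var].dropna(), labels=group_labels, variable=var, welch=welch
            )
            summary0 = f"{cmp.group_stats[0][0]:.1f} ({cmp.group_stats[0][1]:.1f})"
            summary1 = f"{cmp.group_stats[1][0]:.1f} ({cmp.group_stats[1][1]:.1f})"
        rows.append(
            dict(
                variable=var,
                test=cmp.test_name,
                **{f"{group_labels[0]}_n": cmp.group_n[0], f"{group_labels[1]}_n": cmp.group_n[1]},
                **{group_labels[0]: summary0, group_labels[1]: summary1},
                statistic=round(cmp.statistic, 4),
                p_value=round(cmp.p_value, 4),
            )
        )
    return pd.DataFrame(rows)
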