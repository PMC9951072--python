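"""Two-group descriptive comparisons and stratified correlations.

Implements the descriptive workflow used to compare residents with and
without pressure injuries: pooled and Welch two-sample t tests computed from
group summary statistics, Pearson chi-square tests on contingency tables (no
continuity correction), point-biserial correlations of each predictor with
the binary outcome (overall and within Worst-Braden risk category), and a
report assembler that applies a variance-ratio screen to pick the t variant
per attribute.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_VARIANCE_SCREEN = 0.05


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    statistic: float
    kind: str  # pooled_t | welch_t | chi_square
    df: float
    p_value: float
    group_summary: dict = field(default_factory=dict, compare=False)


def _check_groups(sd1, n1, sd2, n2) -> None:
    if n1 < 2 or n2 < 2:
        raise StatsError(f"need n >= 2 per group, got {n1} and {n2}")
    if sd1 < 0 or sd2 < 0:
        raise StatsError("standard deviations must be non-negative")


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variable: str = "",
) -> GroupComparison:
    """Classic equal-variance two-sample t test from summary statistics."""
    _check_groups(sd1, n1, sd2, n2)
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return GroupComparison(
        variable=variable,
        statistic=float(t),
        kind="pooled_t",
        df=float(n1 + n2 - 2),
        p_value=float(p),
        group_summary={"mean": (mean1, mean2), "sd": (sd1, sd2), "n": (n1, n2)},
    )


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variable: str = "",
) -> GroupComparison:
    """Welch unequal-variance t test with Welch-Satterthwaite df."""
    _check_groups(sd1, n1, sd2, n2)
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return GroupComparison(
        variable=variable,
        statistic=float(t),
        kind="welch_t",
        df=float(df),
        p_value=float(p),
        group_summary={"mean": (mean1, mean2), "sd": (sd1, sd2), "n": (n1, n2)},
    )


def chi_square_contingency(
    counts: Sequence[Sequence[float]], variable: str = ""
) -> GroupComparison:
    """Pearson chi-square on an r x c table, df (r-1)(c-1), no correction."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise StatsError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise StatsError("contingency counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("contingency table has a zero marginal row/column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return GroupComparison(
        variable=variable,
        statistic=float(chi2),
        kind="chi_square",
        df=float(df),
        p_value=float(p),
        group_summary={"counts": table.tolist()},
    )


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    r: Optional[float]
    p_value: Optional[float]
    n: int

    @property
    def defined(self) -> bool:
        return self.r is not None


def point_biserial(
    outcome: Sequence[int], predictor: Sequence[float], variable: str = ""
) -> CorrelationResult:
    """Pearson correlation of a numeric predictor with a 0/1 outcome.

    Undefined (constant predictor or single-class outcome) results are
    reported as absent rather than raising.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape:
        raise StatsError("outcome and predictor must have equal length")
    n = len(y)
    if n < 3 or len(np.unique(y)) < 2 or np.ptp(x) == 0:
        return CorrelationResult(variable=variable, r=None, p_value=None, n=n)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(variable=variable, r=float(r), p_value=float(p), n=n)


def point_biserial_by_category(
    outcome: Sequence[int],
    predictor: Sequence[float],
    categories: Sequence[str],
    variable: str = "",
) -> dict[str, CorrelationResult]:
    """Overall plus per-stratum point-biserial correlations.

    Returns a mapping with an ``"overall"`` entry and one entry per distinct
    category (e.g. Worst-Braden risk bands), mirroring a stratified
    correlation table.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    cats = np.asarray(categories)
    out = {"overall": point_biserial(y, x, variable=variable)}
    for cat in pd.unique(cats):
        mask = cats == cat
        out[str(cat)] = point_biserial(y[mask], x[mask], variable=variable)
    return out


def _t_auto(
    mean1, sd1, n1, mean2, sd2, n2, variable: str
) -> GroupComparison:
    """Pooled vs Welch chosen by a two-sided variance-ratio (F) screen."""
    if sd1 == 0 or sd2 == 0:
        return pooled_t(mean1, sd1, n1, mean2, sd2, n2, variable=variable)
    f = (sd1 / sd2) ** 2
    p_hi = stats.f.sf(f, n1 - 1, n2 - 1)
    p = 2 * min(p_hi, 1 - p_hi)
    if p < ALPHA_VARIANCE_SCREEN:
        return welch_t(mean1, sd1, n1, mean2, sd2, n2, variable=variable)
    return pooled_t(mean1, sd1, n1, mean2, sd2, n2, variable=variable)


def table1_report(
    cohort: pd.DataFrame,
    outcome_col: str = "pri",
    continuous: Sequence[str] = (),
    binary: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Group-comparison table for a scored cohort.

    One row per configured attribute: continuous attributes via a two-sample
    t (variance-screened pooled/Welch), binary attributes via a pooled t on
    the 0/1 indicator, categorical attributes via Pearson chi-square on the
    category-by-outcome table.  Degenerate cohorts (a group empty or too
    small) yield rows marked not computable instead of raising.
    """
    y = cohort[outcome_col].astype(int)
    g0 = cohort[y == 0]
    g1 = cohort[y == 1]
    rows = []

    def _row(variable, kind, comp: Optional[GroupComparison]):
        if comp is None:
            rows.append(
                {"variable": variable, "kind": kind, "statistic": math.nan,
                 "df": math.nan, "p_value": math.nan, "computable": False}
            )
        else:
            rows.append(
                {"variable": variable, "kind": comp.kind,
                 "statistic": comp.statistic, "df": comp.df,
                 "p_value": comp.p_value, "computable": True}
            )

    for col in list(continuous) + list(binary):
        if len(g0) < 2 or len(g1) < 2:
            _row(col, "t", None)
            continue
        a, b = g0[col].astype(float), g1[col].astype(float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            _row(col, "t", None)
            continue
        args = (
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        if col in binary:
            _row(col, "t", pooled_t(*args, variable=col))
        else:
            _row(col, "t", _t_auto(*args, variable=col))

    for col in categorical:
        if len(g0) == 0 or len(g1) == 0:
            _row(col, "chi_square", None)
            continue
        table = pd.crosstab(cohort[col], y)
        table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
        if table.shape[0] < 2 or table.shape[1] < 2:
            _row(col, "chi_square", None)
            continue
        _row(col, "chi_square", chi_square_contingency(table.values, variable=col))

    return pd.DataFrame(rows)
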