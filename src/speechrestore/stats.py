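"""Descriptive and inferential statistics for the measure table.

The analysis proceeds measure-table-first: a 3x-IQR outlier fence per
column, descriptives (sample SD, adjusted Fisher-Pearson skewness, excess
kurtosis), Levene's homogeneity test, a Welch one-way ANOVA across the six
sentence conditions (heteroscedasticity-robust, Welch-Satterthwaite
denominator df), pairwise Welch t tests with Benjamini-Hochberg adjustment,
a Pearson correlation screen, and Bonferroni alpha arithmetic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FenceReport",
    "AnovaResult",
    "fence_adjust",
    "describe",
    "levene",
    "welch_anova",
    "pairwise_welch_bh",
    "correlation_screen",
    "bonferroni_alpha",
]


@dataclass(frozen=True)
class FenceReport:
    """Bookkeeping of an IQR outlier screen."""

    k: float
    quartiles: dict  # column -> (Q1, Q3, IQR)
    adjusted_cells: tuple  # (row, column, old, new)

    @property
    def n_adjusted(self) -> int:
        return len(self.adjusted_cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.adjusted_cells), columns=["row", "column", "old", "new"]
        )


@dataclass(frozen=True)
class AnovaResult:
    """Omnibus test outcome plus the per-group moments it used."""

    F: float
    df1: float
    df2: float
    p: float
    group_n: dict
    group_mean: dict
    group_var: dict


def fence_adjust(table: pd.DataFrame, k: float = 3.0, columns=None):
    """Replace values outside ``k`` IQRs beyond the quartiles by Q1/Q3.

    Quartiles use linear interpolation between order statistics. Values
    exactly on a fence are retained. Returns the adjusted copy and a
    :class:`FenceReport`; missing cells are ignored.
    """
    out = table.copy()
    columns = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    quartiles = {}
    adjusted = []
    for col in columns:
        vals = out[col].astype(float)
        present = vals.dropna()
        if present.empty:
            raise ValueError(f"column {col!r} is all-missing")
        if len(present) < 4:
            raise ValueError(f"column {col!r} needs >= 4 values for quartiles")
        q1, q3 = np.quantile(present.to_numpy(), [0.25, 0.75])
        iqr = q3 - q1
        quartiles[col] = (float(q1), float(q3), float(iqr))
        lo, hi = q1 - k * iqr, q3 + k * iqr
        for row, v in vals.dropna().items():
            if v < lo:
                adjusted.append((row, col, float(v), float(q1)))
                out.at[row, col] = q1
            elif v > hi:
                adjusted.append((row, col, float(v), float(q3)))
                out.at[row, col] = q3
    return out, FenceReport(float(k), quartiles, tuple(adjusted))


def describe(column):
    """(mean, sd, min, max, skew, kurtosis) of one measure.

    SD is the sample standard deviation (n-1); skewness is the adjusted
    Fisher-Pearson coefficient and kurtosis is excess (normal -> 0), both
    bias-corrected. Degenerate (zero-variance) input has no defined shape.
    """
    x = np.asarray(pd.Series(column).dropna(), dtype=float)
    if x.size < 3:
        raise ValueError("describe needs at least 3 values")
    if np.var(x) == 0:
        raise ValueError("zero variance: skew/kurtosis undefined")
    return (
        float(np.mean(x)),
        float(np.std(x, ddof=1)),
        float(np.min(x)),
        float(np.max(x)),
        float(sps.skew(x, bias=False)),
        float(sps.kurtosis(x, bias=False)),
    )


def _clean_groups(groups):
    cleaned = [np.asarray(pd.Series(g).dropna(), dtype=float) for g in groups]
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups")
    for g in cleaned:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
    return cleaned


def levene(groups, center: str = "mean"):
    """Levene's homogeneity-of-variances test.

    One-way ANOVA on absolute deviations from each group's center; the
    classic test centers on the mean (default), Brown-Forsythe on the median.
    """
    cleaned = _clean_groups(groups)
    stat, p = sps.levene(*cleaned, center=center)
    return float(stat), float(p)


def welch_anova(groups) -> AnovaResult:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    Groups are weighted by n/s^2; the denominator degrees of freedom follow
    Welch-Satterthwaite, so df2 is fractional in general.
    """
    cleaned = _clean_groups(groups)
    k = len(cleaned)
    n = np.array([g.size for g in cleaned], float)
    m = np.array([g.mean() for g in cleaned])
    v = np.array([g.var(ddof=1) for g in cleaned])
    if np.any(v == 0):
        raise ValueError("zero-variance group: Welch weights undefined")
    w = n / v
    W = w.sum()
    grand = float((w * m).sum() / W)
    a = float((w * (m - grand) ** 2).sum() / (k - 1))
    tail = float((((1 - w / W) ** 2) / (n - 1)).sum())
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * tail
    F = a / b
    df2 = (k**2 - 1) / (3.0 * tail)
    p = float(sps.f.sf(F, k - 1, df2))
    idx = range(k)
    return AnovaResult(
        float(F), float(k - 1), float(df2), p,
        {i: int(n[i]) for i in idx},
        {i: float(m[i]) for i in idx},
        {i: float(v[i]) for i in idx},
    )


def pairwise_welch_bh(groups, labels=None) -> pd.DataFrame:
    """All pairwise Welch t tests with Benjamini-Hochberg adjustment.

    Returns a frame with one row per unordered pair: t, Welch df, raw p and
    the BH step-up adjusted p over all C(g, 2) comparisons.
    """
    cleaned = _clean_groups(groups)
    labels = list(labels) if labels is not None else list(range(len(cleaned)))
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(cleaned), 2):
        res = sps.ttest_ind(a, b, equal_var=False)
        rows.append({
            "group_a": labels[i],
            "group_b": labels[j],
            "t": float(res.statistic),
            "df": float(res.df),
            "p_raw": float(res.pvalue),
        })
    df = pd.DataFrame(rows)
    if len(df) == 1:
        df["p_adj"] = df["p_raw"]
    else:
        df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df


def correlation_screen(table: pd.DataFrame, columns=None):
    """Pearson r and two-sided p for every pair of measures.

    Pairwise complete observations; the r matrix is symmetric with unit
    diagonal. A zero-variance column has no defined correlation.
    """
    columns = list(columns) if columns is not None else list(table.columns)
    r = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((len(columns), len(columns))), index=columns, columns=columns)
    np.fill_diagonal(p.values, np.nan)
    for a, b in itertools.combinations(columns, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete observations for ({a}, {b})")
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero-variance column in pair ({a}, {b})")
        res = sps.pearsonr(x, y)
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p


def bonferroni_alpha(base_alpha: float, m: int) -> float:
    """Bonferroni-adjusted test level: base alpha divided by m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(base_alpha) / int(m)
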