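"""Group comparisons: factorial ANOVA, Tukey–Kramer post hoc tests and
log-normal distribution summaries.

The experimental designs this serves are crossed categorical factors —
composition (collagen vs collagen/chitosan blends), crosslinking,
scaffold section (bottom/middle/top), laminin functionalization, time —
with a numeric response such as pore area, modulus or fluorescence.
ANOVA terms come from an OLS fit (statsmodels); all-pairs comparisons
use the studentized-range distribution with the Kramer unequal-n
correction.  Significance stars follow the usual legend: ns p > 0.05,
* p < 0.05, ** p < 0.01, *** p < 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "FactorialDataset",
    "ComparisonResult",
    "anova_factorial",
    "tukey_kramer",
    "lognormal_summary",
    "significance_stars",
]


@dataclass
class FactorialDataset:
    """Tidy response + categorical factor columns for a crossed design."""

    data: pd.DataFrame
    response: str
    factors: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in [self.response, *self.factors]
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"columns not in data: {missing}")
        if self.data[[self.response, *self.factors]].isna().any().any():
            raise ValueError("missing values in response or factors")
        for f in self.factors:
            if self.data[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than 2 levels")


@dataclass
class ComparisonResult:
    term: str
    statistic: float  # F
    p_value: float
    df: float
    pairwise: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def significance_stars(p: float) -> str:
    """Map an (adjusted) p-value to the standard star legend."""
    if not np.isfinite(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova_factorial(ds: FactorialDataset, max_order: int | None = None,
                    ss_type: int = 2) -> list[ComparisonResult]:
    """Factorial ANOVA with interactions up to ``max_order``.

    ``max_order`` defaults to the full factorial (all interactions).
    Unbalanced designs are handled by the chosen sum-of-squares type
    (Type II default; 1 and 3 selectable), which is recorded in each
    result's metadata for the report.
    """
    k = len(ds.factors)
    if max_order is None:
        max_order = k
    if not (1 <= max_order <= k):
        raise ValueError("max_order must be between 1 and the factor count")
    terms = " + ".join(f"C(Q('{f}'))" for f in ds.factors)
    rhs = f"({terms}) ** {max_order}" if max_order > 1 and k > 1 else terms
    model = ols(f"Q('{ds.response}') ~ {rhs}", data=ds.data).fit()
    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom; design saturated")
    table = sm.stats.anova_lm(model, typ=ss_type)
    results = []
    for term, row in table.iterrows():
        if term.strip() == "Residual":
            continue
        label = (term.replace("C(Q('", "").replace("'))", "")
                 .replace(":", " x "))
        results.append(
            ComparisonResult(
                term=label,
                statistic=float(row["F"]),
                p_value=float(row["PR(>F)"]),
                df=float(row["df"]),
                meta={"ss_type": ss_type, "df_resid": float(model.df_resid)},
            )
        )
    return results


def tukey_kramer(ds: FactorialDataset, factor: str) -> pd.DataFrame:
    """All-pairs mean comparison on one factor (Tukey–Kramer).

    Returns one row per level pair with the mean difference, the
    unadjusted pooled-t p-value, the studentized-range adjusted p-value
    (with the Kramer 1/n_i + 1/n_j correction for unequal group sizes),
    the star code, and a 0.05 significance flag.  The error variance is
    the one-way MSE pooled across all levels of ``factor``.
    """
    if factor not in ds.factors:
        raise ValueError(f"{factor!r} is not a declared factor")
    g = ds.data.groupby(factor, observed=True)[ds.response]
    levels = list(g.groups)
    if len(levels) < 2:
        raise ValueError("factor must have at least 2 levels")
    counts = g.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"levels with fewer than 2 observations: {bad}")
    means = g.mean()
    k = len(levels)
    n_total = int(counts.sum())
    df = n_total - k
    mse = float(((g.apply(lambda v: ((v - v.mean()) ** 2).sum())).sum()) / df)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(means[b] - means[a])
            se = np.sqrt(mse * (1.0 / counts[a] + 1.0 / counts[b]))
            if se == 0:
                t = 0.0 if diff == 0 else np.inf
            else:
                t = diff / se
            p_raw = float(2.0 * sps.t.sf(abs(t), df))
            q = abs(t) * np.sqrt(2.0)
            p_adj = float(sps.studentized_range.sf(q, k, df))
            p_adj = min(max(p_adj, 0.0), 1.0)
            rows.append(
                {
                    "level_a": a,
                    "level_b": b,
                    "mean_diff": diff,
                    "se": float(se),
                    "p_unadjusted": p_raw,
                    "p_adjusted": p_adj,
                    "stars": significance_stars(p_adj),
                    "significant_0.05": bool(p_adj < 0.05),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["factor"] = factor
    out.attrs["df"] = df
    out.attrs["mse"] = mse
    return out


def lognormal_summary(values: np.ndarray | pd.Series) -> dict:
    """Fit a log-normal to positive data and test the fit on log-values.

    Returns the log-scale mean/SD with standard errors, the geometric
    mean/SD, and a normality test p-value on the logs (D'Agostino K²;
    Shapiro–Wilk for n < 8 is not attempted — a warning is emitted and
    the p is NaN).  All-equal samples get a ``degenerate`` flag.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty sample")
    if (v <= 0).any():
        raise ValueError("log-normal summary requires positive values")
    logs = np.log(v)
    log_mean = float(logs.mean())
    log_sd = float(logs.std(ddof=1)) if v.size > 1 else 0.0
    degenerate = bool(np.allclose(logs, logs[0]))
    if degenerate or v.size < 8:
        if not degenerate:
            warnings.warn("n < 8: goodness-of-fit test skipped", stacklevel=2)
        gof_p = float("nan")
    else:
        gof_p = float(sps.normaltest(logs).pvalue)
    return {
        "n": int(v.size),
        "log_mean": log_mean,
        "log_sd": log_sd,
        "log_mean_se": log_sd / np.sqrt(v.size),
        "geometric_mean": float(np.exp(log_mean)),
        "geometric_sd": float(np.exp(log_sd)),
        "gof_p": gof_p,
        "degenerate": degenerate,
    }
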