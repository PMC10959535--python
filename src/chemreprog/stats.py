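"""Shared statistical primitives.

Thin, validated wrappers around scipy/statsmodels used by every other
module: Welch's t, one-way ANOVA, Benjamini-Hochberg adjustment, Spearman
correlation, the exact hypergeometric upper tail, and a generic
feature-by-feature group screen (the shape of the metabolite screen).

Degenerate inputs are handled explicitly rather than propagating NaNs:
two constant, equal groups give t = 0 / p = 1, and constant groups with
different means give p = 0 with a ``zero_variance`` warning flag so that
synthetic edge cases cannot crash a pipeline run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "TestResult",
    "welch_t",
    "anova_oneway",
    "bh_adjust",
    "spearman_rho",
    "hypergeom_tail",
    "pairwise_welch",
    "feature_screen",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    warning: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}")


def _as_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if arr.size < 2:
        raise ValidationError(f"{name} needs at least 2 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def welch_t(x, y) -> TestResult:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom.

    Zero-variance groups: equal means return (t=0, p=1); differing means
    return p=0 flagged ``zero_variance`` instead of raising.
    """
    x = _as_group(x, "x")
    y = _as_group(y, "y")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, p_value=1.0, df=float(x.size + y.size - 2))
        return TestResult(
            statistic=np.inf if x.mean() > y.mean() else -np.inf,
            p_value=0.0,
            df=float(x.size + y.size - 2),
            warning="zero_variance",
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), df=float(res.df))


def anova_oneway(groups) -> TestResult:
    """One-way fixed-effects ANOVA (classical equal-variance F test)."""
    arrays = [_as_group(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    pooled = np.concatenate(arrays)
    df1 = len(arrays) - 1
    df2 = pooled.size - len(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0, df=float(df1), extra={"df2": float(df2)})
    res = sps.f_oneway(*arrays)
    stat = float(res.statistic)
    pv = float(res.pvalue)
    if np.isnan(stat):  # within-group variance all zero, means differ
        return TestResult(statistic=np.inf, p_value=0.0, df=float(df1),
                          warning="zero_variance", extra={"df2": float(df2)})
    return TestResult(statistic=stat, p_value=pv, df=float(df1), extra={"df2": float(df2)})


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("length mismatch between x and y")
    if x.size < 3:
        raise ValidationError("need at least 3 paired observations")
    return float(sps.spearmanr(x, y).statistic)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact one-sided upper tail P(X >= k).

    X counts successes in a draw of ``n`` from a population of ``N``
    containing ``K`` successes (R's ``phyper(k-1, K, N-K, n, lower=FALSE)``).
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer")
    if not (k <= min(K, n) and K <= N and n <= N):
        raise ValidationError(f"inconsistent margins: k={k}, K={K}, n={n}, N={N}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def pairwise_welch(groups: dict[str, np.ndarray],
                   pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """All pairwise Welch t-tests with one BH family across the pairs.

    Serves as the post-hoc step after a significant one-way ANOVA.
    """
    if pairs is None:
        pairs = list(itertools.combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        res = welch_t(groups[a], groups[b])
        rows.append({"group_a": a, "group_b": b,
                     "effect": float(np.mean(groups[a]) - np.mean(groups[b])),
                     "statistic": res.statistic, "df": res.df, "p_value": res.p_value})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out


def feature_screen(matrix: pd.DataFrame, groups: dict[str, str],
                   transform: str = "log", fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Per-feature one-way ANOVA across sample groups with BH correction.

    ``matrix`` is feature x sample. ``transform='log'`` applies natural log
    (all values must be positive); 'none' leaves values as-is. Returns a
    DataFrame indexed by feature with statistic, p_value, fdr, significant.
    """
    if transform not in ("log", "none"):
        raise ValidationError(f"unknown transform: {transform}")
    missing = [s for s in matrix.columns if s not in groups]
    if missing:
        raise ValidationError(f"samples without group labels: {missing[:5]}")
    labels = pd.Series({s: groups[s] for s in matrix.columns})
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValidationError("need >=2 groups with >=2 samples each")
    values = matrix.to_numpy(dtype=float)
    if transform == "log":
        if np.any(values <= 0):
            raise ValidationError("log transform requires strictly positive values")
        values = np.log(values)
    group_cols = {g: np.flatnonzero((labels == g).to_numpy()) for g in counts.index}
    stats_, pvals = [], []
    for row in values:
        res = anova_oneway([row[idx] for idx in group_cols.values()])
        stats_.append(res.statistic)
        pvals.append(res.p_value)
    out = pd.DataFrame({"statistic": stats_, "p_value": pvals}, index=matrix.index)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["fdr"] < fdr_cutoff
    return out
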