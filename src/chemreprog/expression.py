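"""Gene-count filtering, RLE normalization, differential expression.

Genes are kept when at least ``min_fraction`` of the samples have at least
``min_reads`` counts (boundary inclusive). Size factors follow the
relative-log-expression (median-of-ratios) scheme: for each sample the
median, over genes expressed in every sample, of count / geometric mean.
Differential expression is a per-gene Welch t-test on log2(normalized + 1)
with the log-fold change defined as the difference of group means on that
scale and BH adjustment across tested genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import NormalizationError, ValidationError
from .stats import bh_adjust, welch_t

__all__ = ["filter_genes", "rle_normalize", "differential_expression"]


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.empty:
        raise ValidationError("empty counts matrix")
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValidationError("counts matrix contains negative entries")


def filter_genes(counts: pd.DataFrame, min_reads: int = 5,
                 min_fraction: float = 0.2) -> pd.DataFrame:
    """Keep genes with >= ``min_reads`` counts in >= ``min_fraction`` of samples."""
    _check_counts(counts)
    frac = (counts >= min_reads).sum(axis=1) / counts.shape[1]
    return counts.loc[frac >= min_fraction]


def rle_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization; returns (normalized, size_factors).

    Reference genes are those with strictly positive counts in all
    samples; raises when none exists.
    """
    _check_counts(counts)
    values = counts.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise NormalizationError("no gene with positive counts in every sample")
    ref = values[reference]
    geo_mean = np.exp(np.log(ref).mean(axis=1))
    size_factors = np.median(ref / geo_mean[:, None], axis=0)
    normalized = counts / size_factors
    return normalized, pd.Series(size_factors, index=counts.columns, name="size_factor")


def differential_expression(normalized: pd.DataFrame, groups: dict[str, str],
                            control: str, treated: str) -> pd.DataFrame:
    """Per-gene Welch t on log2(normalized + 1); lfc = treated - control means.

    Returns a DataFrame indexed by gene with columns lfc, pv, fdr.
    """
    labels = pd.Series({s: groups.get(s) for s in normalized.columns})
    x_cols = labels[labels == treated].index
    y_cols = labels[labels == control].index
    if len(x_cols) < 2 or len(y_cols) < 2:
        raise ValidationError("each group needs at least 2 samples")
    logged = np.log2(normalized + 1.0)
    x = logged[x_cols].to_numpy()
    y = logged[y_cols].to_numpy()
    lfc = x.mean(axis=1) - y.mean(axis=1)
    pvals = np.empty(len(logged))
    for i in range(len(logged)):
        pvals[i] = welch_t(x[i], y[i]).p_value
    out = pd.DataFrame({"lfc": lfc, "pv": pvals}, index=normalized.index)
    out["fdr"] = bh_adjust(out["pv"].to_numpy())
    return out
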