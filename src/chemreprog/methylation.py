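"""DNA-methylation differential analysis and chromatin-state enrichment.

Beta values (methylated fraction, [0,1]) are converted to M-values,
M = log2(beta / (1 - beta)) after clamping beta into [eps, 1 - eps].
Differentially methylated probes (DMPs) come from per-probe Welch tests
on M with lfcM = difference of group means, selected at |lfcM| > 1 and
BH FDR < 0.05. State enrichment builds, per (chromatin state, direction),
the 2x2 table of in-state vs not x DMP vs not over the analysis universe,
reports the odds ratio (Haldane +0.5 when a cell is empty) and a one-sided
hypergeometric p — upper tail for enrichment (OR > 1), lower tail for
depletion — BH-adjusted over all states x directions and reported as
signed log10 adjusted p (+ for enrichment, - for depletion).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .stats import bh_adjust, hypergeom_tail, welch_t

__all__ = [
    "filter_probes",
    "beta_to_m",
    "differential_methylation",
    "mean_methylation",
    "chromatin_state_enrichment",
]


def filter_probes(beta: pd.DataFrame,
                  detection: pd.DataFrame | None = None,
                  detection_cutoff: float = 0.01) -> pd.DataFrame:
    """Drop probes with any missing value or any detection p > cutoff."""
    if beta.index.has_duplicates:
        raise ValidationError("duplicate probe identifiers")
    keep = beta.notna().all(axis=1)
    if detection is not None:
        if not (detection.index.equals(beta.index)
                and detection.columns.equals(beta.columns)):
            raise ValidationError("detection matrix not aligned with beta matrix")
        keep &= (detection <= detection_cutoff).all(axis=1)
    out = beta.loc[keep]
    values = out.to_numpy(dtype=float)
    if ((values < 0) | (values > 1)).any():
        raise ValidationError("beta values outside [0, 1]")
    return out


def beta_to_m(beta, eps: float = 1e-6):
    """M = log2(beta / (1 - beta)) with beta clamped into [eps, 1 - eps]."""
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError("beta values outside [0, 1]")
    clamped = np.clip(arr, eps, 1.0 - eps)
    m = np.log2(clamped / (1.0 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m if m.shape else float(m)


def differential_methylation(m_values: pd.DataFrame, groups: dict[str, str],
                             control: str, treated: str,
                             lfc_cutoff: float = 1.0,
                             fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Per-probe two-group test on M-values; DMPs per the published cutoffs.

    Returns a probe-indexed DataFrame with lfcM, pv, fdr, direction
    (hyper/hypo by sign of lfcM) and the selected flag
    (|lfcM| > lfc_cutoff and fdr < fdr_cutoff).
    """
    labels = pd.Series({s: groups.get(s) for s in m_values.columns})
    x_cols = labels[labels == treated].index
    y_cols = labels[labels == control].index
    if len(x_cols) < 2 or len(y_cols) < 2:
        raise ValidationError("each group needs at least 2 samples")
    x = m_values[x_cols].to_numpy(dtype=float)
    y = m_values[y_cols].to_numpy(dtype=float)
    lfc = x.mean(axis=1) - y.mean(axis=1)
    pvals = np.array([welch_t(x[i], y[i]).p_value for i in range(len(m_values))])
    out = pd.DataFrame({"lfcM": lfc, "pv": pvals}, index=m_values.index)
    out["fdr"] = bh_adjust(pvals)
    out["direction"] = np.where(lfc >= 0, "hyper", "hypo")
    out["selected"] = (np.abs(lfc) > lfc_cutoff) & (out["fdr"] < fdr_cutoff)
    return out


def mean_methylation(beta: pd.DataFrame) -> pd.Series:
    """Arithmetic mean beta per sample."""
    if beta.empty:
        raise ValidationError("empty beta matrix")
    return beta.mean(axis=0)


def chromatin_state_enrichment(dmps: pd.DataFrame, universe: pd.Index,
                               state_map: pd.Series) -> pd.DataFrame:
    """Odds ratio and signed log10 adjusted p per (state, direction).

    ``dmps`` is the differential_methylation output (only selected rows
    are used); ``universe`` the analysis probe set; ``state_map`` maps
    probe -> chromatin state (probes absent from the map are ignored for
    state membership but stay in the universe). Enrichment and depletion
    are opposite one-sided hypergeometric tails chosen by the OR, all
    entering one BH family.
    """
    selected = dmps[dmps["selected"]]
    outside = selected.index.difference(universe)
    if len(outside):
        raise ValidationError(f"DMPs outside the universe: {list(outside[:5])}")
    if state_map.index.has_duplicates:
        raise ValidationError("state map assigns multiple states to one probe")
    n_total = len(universe)
    states = sorted(state_map.loc[state_map.index.intersection(universe)].unique())

    rows = []
    for direction in ("hyper", "hypo"):
        dmp_set = set(selected.index[selected["direction"] == direction])
        n_dmp = len(dmp_set)
        for state in states:
            in_state = set(state_map.index[state_map == state]) & set(universe)
            k = len(dmp_set & in_state)          # DMPs of this direction in state
            K = len(in_state)                    # universe probes in state
            a, b = k, n_dmp - k
            c, d = K - k, n_total - K - (n_dmp - k)
            if min(a, b, c, d) == 0:
                odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                odds = (a * d) / (b * c)
            if odds > 1:
                p = hypergeom_tail(k, K, n_dmp, n_total)
            else:
                p = float(sps.hypergeom.cdf(k, n_total, K, n_dmp))
            rows.append({"state": state, "direction": direction,
                         "n_state": K, "n_dmp": n_dmp, "overlap": k,
                         "odds_ratio": odds, "p_value": p})
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    sign = np.where(out["odds_ratio"] > 1, 1.0, -1.0)
    with np.errstate(divide="ignore"):
        out["signed_log10_adj_p"] = sign * (-np.log10(out["adj_p"]))
    return out
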