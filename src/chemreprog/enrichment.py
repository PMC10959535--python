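"""Signed ranking metric, pre-ranked GSEA, signatures, and their association.

Genes are ranked by the signed metric -log10(pv) x sgn(lfc). For a gene
set S in a universe of N ranked genes, the enrichment score ES is the
signed extremum of the weighted running sum that increments by
|metric|^weight (normalized over in-set genes) at hits and decrements by
1/(N - |S|) at misses. The null is fgsea-style: random same-size gene
sets drawn from the universe with a seeded generator; the p-value is the
add-one fraction of same-sign null ES at least as extreme, and NES is ES
divided by the mean |null ES| of the same sign. BH adjustment runs across
the sets of one call.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import bh_adjust, spearman_rho

__all__ = [
    "ranking_metric",
    "rank_genes",
    "enrichment_score",
    "gsea_preranked",
    "build_signature",
    "signature_association",
    "signature_correlation",
    "read_gmt",
    "write_gmt",
]

PV_FLOOR = 1e-300


def ranking_metric(pv: float, lfc: float, pv_floor: float = PV_FLOOR) -> float:
    """Signed ranking metric -log10(pv) x sgn(lfc)."""
    if not (0.0 < pv <= 1.0):
        raise ValidationError(f"p-value must lie in (0, 1], got {pv}")
    if not np.isfinite(lfc):
        raise ValidationError(f"logFC must be finite, got {lfc}")
    return -math.log10(max(pv, pv_floor)) * float(np.sign(lfc))


def rank_genes(de: pd.DataFrame, pv_floor: float = PV_FLOOR) -> pd.Series:
    """Ranked list from a DE table (index = gene, columns pv and lfc).

    Descending by metric; ties broken by gene identifier for determinism.
    """
    metric = pd.Series(
        [ranking_metric(pv, lfc, pv_floor) for pv, lfc in zip(de["pv"], de["lfc"])],
        index=de.index, name="metric")
    order = sorted(metric.index, key=lambda g: (-metric[g], str(g)))
    return metric.loc[order]


def enrichment_score(metrics: np.ndarray, hit_mask: np.ndarray,
                     weight: float = 1.0) -> float:
    """ES of one set: signed extremum of the weighted running sum."""
    n = len(metrics)
    m = int(hit_mask.sum())
    if m == 0 or m == n:
        raise ValidationError("gene set must be a proper non-empty subset of the universe")
    w = np.abs(metrics) ** weight if weight != 0 else np.ones_like(metrics, dtype=float)
    nr = w[hit_mask].sum()  # masked sum: no zero terms perturbing rounding
    if nr == 0:  # all in-set metrics are exactly zero
        hit_steps = np.where(hit_mask, 1.0 / m, 0.0)
    else:
        hit_steps = np.where(hit_mask, w / nr, 0.0)
    miss_steps = np.where(hit_mask, 0.0, 1.0 / (n - m))
    running = np.cumsum(hit_steps - miss_steps)
    return float(running[np.argmax(np.abs(running))])


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """ES evaluated only at its candidate extremes (positions sorted, 0-based)."""
    m = len(positions)
    hw = weights[positions]
    nr = hw.sum()
    cum = np.cumsum(hw) / nr if nr > 0 else np.arange(1, m + 1) / m
    miss = 1.0 / (n - m)
    after = cum - (positions - np.arange(m)) * miss
    before = after - (hw / nr if nr > 0 else 1.0 / m)
    cand = np.concatenate([after, before])
    return float(cand[np.argmax(np.abs(cand))])


def gsea_preranked(ranked: pd.Series, sets: dict[str, set], n_perm: int = 5000,
                   seed: int = 0, weight: float = 1.0, min_size: int = 5,
                   fdr_cutoff: float = 0.1) -> pd.DataFrame:
    """Pre-ranked GSEA of every set against one ranked list.

    Returns a DataFrame (one row per set, sorted by name) with columns
    set, size, es, nes, p_value, fdr, significant, error. Sets disjoint
    from (or too small in) the universe get an error record; the run
    continues.
    """
    genes = list(ranked.index)
    if len(genes) != len(set(genes)):
        raise ValidationError("ranked list contains duplicate genes")
    metrics = ranked.to_numpy(dtype=float)
    if not np.all(np.isfinite(metrics)):
        raise ValidationError("ranked metrics must be finite")
    n = len(genes)
    index_of = {g: i for i, g in enumerate(genes)}
    w = np.abs(metrics) ** weight if weight != 0 else np.ones(n)

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_for_size(m: int) -> np.ndarray:
        if m not in null_cache:
            null = np.empty(n_perm)
            for i in range(n_perm):
                pos = np.sort(rng.choice(n, size=m, replace=False))
                null[i] = _es_from_positions(pos, w, n)
            null_cache[m] = null
        return null_cache[m]

    rows = []
    for name in sorted(sets):
        members = [index_of[g] for g in sets[name] if g in index_of]
        size = len(members)
        if size < min_size or size == n:
            rows.append({"set": name, "size": size, "es": np.nan, "nes": np.nan,
                         "p_value": np.nan,
                         "error": f"set size {size} outside ({min_size - 1}, {n})"})
            continue
        pos = np.array(sorted(members))
        es = _es_from_positions(pos, w, n)
        null = null_for_size(size)
        same_sign = null[null > 0] if es >= 0 else null[null < 0]
        n_extreme = int(np.sum(np.abs(same_sign) >= abs(es)))
        p = (1 + n_extreme) / (1 + len(same_sign))
        nes = es / np.mean(np.abs(same_sign)) if len(same_sign) else 0.0
        rows.append({"set": name, "size": size, "es": es, "nes": nes,
                     "p_value": p, "error": ""})
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    valid = out["p_value"].notna()
    if valid.any():
        out.loc[valid, "fdr"] = bh_adjust(out.loc[valid, "p_value"].to_numpy())
    out["significant"] = valid & (out["fdr"] < fdr_cutoff)
    return out


def build_signature(de: pd.DataFrame, n: int = 500, adj_cutoff: float = 0.05,
                    split: bool = False):
    """Top-``n`` significant genes by |logFC| as a gene-set signature.

    Among genes with fdr < ``adj_cutoff``, the ``n`` with largest absolute
    lfc (all of them if fewer qualify). ``split=True`` returns (up, down)
    sets partitioned by lfc sign instead of one set.
    """
    if de.empty:
        raise ValidationError("empty DE table")
    sig = de[de["fdr"] < adj_cutoff]
    order = sorted(sig.index, key=lambda g: (-abs(sig.at[g, "lfc"]), str(g)))
    top = order[:n]
    if not split:
        return set(top)
    up = {g for g in top if sig.at[g, "lfc"] > 0}
    down = {g for g in top if sig.at[g, "lfc"] < 0}
    return up, down


def signature_association(de_tables: dict[str, pd.DataFrame],
                          signatures: dict[str, set], n_perm: int = 5000,
                          seed: int = 0, weight: float = 1.0,
                          min_size: int = 5) -> pd.DataFrame:
    """NES/FDR matrix of every condition's ranked list against every signature.

    One GSEA call per condition (BH across signatures within a condition);
    the ``stars`` column marks FDR < 0.05 / 0.01 / 0.001.
    """
    frames = []
    for cond in sorted(de_tables):
        ranked = rank_genes(de_tables[cond])
        res = gsea_preranked(ranked, signatures, n_perm=n_perm, seed=seed,
                             weight=weight, min_size=min_size)
        res.insert(0, "condition", cond)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out["stars"] = [
        "" if not np.isfinite(f) else "***" if f < 0.001 else "**" if f < 0.01
        else "*" if f < 0.05 else ""
        for f in out["fdr"]
    ]
    return out


def signature_correlation(de_a: pd.DataFrame, de_b: pd.DataFrame,
                          n: int = 650) -> float:
    """Spearman rho of lfc over the union of each table's top-n genes by p.

    The union is restricted to genes present in both tables.
    """
    shared = de_a.index.intersection(de_b.index)
    if shared.empty:
        raise ValidationError("no shared genes between DE tables")
    a = de_a.loc[shared]
    b = de_b.loc[shared]
    top_a = sorted(a.index, key=lambda g: (a.at[g, "pv"], str(g)))[:n]
    top_b = sorted(b.index, key=lambda g: (b.at[g, "pv"], str(g)))[:n]
    union = sorted(set(top_a) | set(top_b))
    if len(union) < 3:
        raise ValidationError("gene union smaller than 3")
    return spearman_rho(a.loc[union, "lfc"].to_numpy(),
                        b.loc[union, "lfc"].to_numpy())


# -- GMT I/O ----------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set]:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: expected name, description, >=1 member")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
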