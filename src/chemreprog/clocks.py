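"""Linear transcriptomic age clocks: apply, impute, compare groups.

A clock is an intercept plus per-gene weights over z-scaled
log2(expression + 1), with the z-scaling anchored to the clock's training
statistics (mean, sd per gene) stored in the model file. Clock genes
absent from the data are imputed with the model's precalculated average
value on the log scale before scaling:

    tAge = intercept + sum_g w_g * (x_g - mean_g) / sd_g,   x_g = log2(e_g + 1)

Group contrasts on predicted ages use independent (Welch) t-tests per
treatment-vs-control pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .stats import pairwise_welch

__all__ = ["ClockModel", "apply_clock", "compare_tages",
           "read_clock", "write_clock"]


@dataclass
class ClockModel:
    intercept: float
    genes: pd.DataFrame  # index gene; columns weight, training_mean, training_sd, imputation_value

    def __post_init__(self) -> None:
        required = {"weight", "training_mean", "training_sd", "imputation_value"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValidationError(f"clock model missing columns: {sorted(missing)}")
        if self.genes.index.has_duplicates:
            raise ValidationError("clock gene identifiers must be unique")
        if (self.genes["training_sd"] <= 0).any():
            raise ValidationError("training_sd must be strictly positive")


def apply_clock(expr: pd.DataFrame, clock: ClockModel,
                scaling: str = "training") -> pd.DataFrame:
    """Predict tAge per sample from a normalized gene x sample matrix.

    ``scaling='training'`` (default) z-scales against the clock's stored
    training statistics; ``'per_sample'`` standardizes each sample's
    clock-gene vector instead. Returns a DataFrame indexed by sample with
    columns tAge, n_imputed, fully_imputed.
    """
    if scaling not in ("training", "per_sample"):
        raise ValidationError(f"unknown scaling mode {scaling!r}")
    if (expr.to_numpy() < 0).any():
        raise ValidationError("expression matrix contains negative values")
    genes = clock.genes
    present = genes.index.intersection(expr.index)
    n_imputed = len(genes) - len(present)

    logged = pd.DataFrame(
        np.tile(genes["imputation_value"].to_numpy()[:, None], (1, expr.shape[1])),
        index=genes.index, columns=expr.columns)
    if len(present):
        logged.loc[present] = np.log2(expr.loc[present] + 1.0)

    if scaling == "training":
        z = logged.sub(genes["training_mean"], axis=0).div(genes["training_sd"], axis=0)
    else:
        z = (logged - logged.mean(axis=0)) / logged.std(axis=0, ddof=1)
    tage = clock.intercept + z.mul(genes["weight"], axis=0).sum(axis=0)
    return pd.DataFrame({
        "tAge": tage,
        "n_imputed": n_imputed,
        "fully_imputed": n_imputed == len(genes),
    })


def compare_tages(preds: pd.DataFrame, groups: dict[str, str],
                  pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Welch t-test of mean tAge for each (treated, control) pair.

    ``pairs`` lists (group_a, group_b) label pairs, e.g. one treatment vs
    its control within an age stratum; effect = mean(a) - mean(b).
    """
    by_group: dict[str, np.ndarray] = {}
    for sample, label in groups.items():
        if sample not in preds.index:
            raise ValidationError(f"sample {sample!r} has no prediction")
        by_group.setdefault(label, []).append(preds.at[sample, "tAge"])
    by_group = {k: np.asarray(v, dtype=float) for k, v in by_group.items()}
    for a, b in pairs:
        for label in (a, b):
            if label not in by_group:
                raise ValidationError(f"unknown group label {label!r}")
            if len(by_group[label]) < 2:
                raise ValidationError(f"group {label!r} has fewer than 2 samples")
    return pairwise_welch(by_group, pairs=pairs)


# -- model file I/O ---------------------------------------------------------

def read_clock(path: str | Path) -> ClockModel:
    """Clock TSV: '#intercept=<float>' header line, then per-gene rows."""
    intercept = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#intercept="):
                intercept = float(line.strip().split("=", 1)[1])
            if not line.startswith("#"):
                break
    if intercept is None:
        raise ParseError("clock file lacks an '#intercept=' header line")
    genes = pd.read_csv(path, sep="\t", comment="#", index_col="gene")
    genes.index.name = None
    return ClockModel(intercept=intercept, genes=genes)


def write_clock(clock: ClockModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#intercept={clock.intercept}\n")
        clock.genes.to_csv(fh, sep="\t", index_label="gene")
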