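"""Alternative-splicing events, Psi quantification, differential splicing.

Percent spliced-in for one event in one sample is the length-normalized
junction-count ratio

    psi = (I / l_I) / (I / l_I + S / l_S)

with I and S the inclusion- and skipping-supporting read counts and l_I,
l_S the effective lengths of the two forms. Events are tested between two
replicate groups with Welch's t on per-replicate Psi, BH-adjusted across
the tested events, and selected at |dPsi| > 0.1 together with either
FDR < 0.05 (default) or p < 0.05 (the alternative published variant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import bh_adjust, welch_t

__all__ = [
    "EVENT_TYPES",
    "SpliceEvent",
    "compute_psi",
    "psi_matrix",
    "differential_splicing",
    "direction_summary",
    "read_junction_counts",
    "read_events",
    "write_events",
]

EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")


@dataclass
class SpliceEvent:
    """One alternative-splicing event anchored to a host transcript.

    ``alt_region`` holds the genomic interval(s) of the alternative
    segment, 0-based half-open: one interval for SE/RI/A5SS/A3SS, two for
    MXE (the pair of mutually exclusive exons; the first listed is the
    one carried by the inclusion form).
    """

    event_id: str
    type: str
    gene_id: str
    transcript_id: str
    alt_region: list[tuple[int, int]]
    len_inclusion: float
    len_skipping: float

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValidationError(f"{self.event_id}: unknown event type {self.type!r}")
        n_expected = 2 if self.type == "MXE" else 1
        if len(self.alt_region) != n_expected:
            raise ValidationError(
                f"{self.event_id}: {self.type} needs {n_expected} alt interval(s)")
        for a, b in self.alt_region:
            if a >= b:
                raise ValidationError(f"{self.event_id}: empty alt interval ({a}, {b})")
        if self.len_inclusion <= 0 or self.len_skipping <= 0:
            raise ValidationError(f"{self.event_id}: effective lengths must be positive")


def compute_psi(inclusion: int, skipping: int, len_inclusion: float,
                len_skipping: float, min_coverage: int = 10) -> float:
    """Length-normalized Psi for one (event, sample); NaN below coverage."""
    if inclusion < 0 or skipping < 0:
        raise ValidationError("junction counts must be non-negative")
    if len_inclusion <= 0 or len_skipping <= 0:
        raise ValidationError("effective lengths must be positive")
    if inclusion + skipping < min_coverage or inclusion + skipping == 0:
        return math.nan
    ni = inclusion / len_inclusion
    ns = skipping / len_skipping
    return ni / (ni + ns)


def psi_matrix(counts: pd.DataFrame, min_coverage: int = 10) -> pd.DataFrame:
    """Per-(event, sample) Psi and coverage from a long junction-count table.

    ``counts`` columns: event_id, sample, inclusion_count, skipping_count,
    len_inclusion, len_skipping. Returns a long DataFrame with columns
    event_id, sample, psi, coverage (psi is NaN below ``min_coverage``).
    """
    required = {"event_id", "sample", "inclusion_count", "skipping_count",
                "len_inclusion", "len_skipping"}
    missing = required - set(counts.columns)
    if missing:
        raise ValidationError(f"junction table missing columns: {sorted(missing)}")
    psi = [
        compute_psi(int(r.inclusion_count), int(r.skipping_count),
                    float(r.len_inclusion), float(r.len_skipping), min_coverage)
        for r in counts.itertuples()
    ]
    return pd.DataFrame({
        "event_id": counts["event_id"].to_numpy(),
        "sample": counts["sample"].to_numpy(),
        "psi": psi,
        "coverage": (counts["inclusion_count"] + counts["skipping_count"]).to_numpy(),
    })


def differential_splicing(psi: pd.DataFrame, groups: dict[str, str],
                          control: str, treated: str,
                          delta_cutoff: float = 0.1, fdr_cutoff: float = 0.05,
                          use_pvalue: bool = False,
                          min_replicates: int = 2) -> pd.DataFrame:
    """Two-group differential-splicing test on replicate-level Psi.

    dPsi = mean(treated) - mean(control); Welch t per event; BH across the
    tested events. Events with fewer than ``min_replicates`` non-missing
    Psi values in either group are reported with tested=False and excluded
    from the BH family. Selection: |dPsi| > delta_cutoff and FDR <
    fdr_cutoff (or p < fdr_cutoff when ``use_pvalue``).
    """
    unknown = sorted(set(groups.values()) - {control, treated})
    if unknown:
        raise ValidationError(f"unknown group labels: {unknown}")
    labeled = psi[psi["sample"].map(groups).notna()].copy()
    labeled["group"] = labeled["sample"].map(groups)

    rows = []
    for event_id, sub in labeled.groupby("event_id", sort=True):
        x = sub.loc[(sub["group"] == treated) & sub["psi"].notna(), "psi"].to_numpy()
        y = sub.loc[(sub["group"] == control) & sub["psi"].notna(), "psi"].to_numpy()
        if len(x) < min_replicates or len(y) < min_replicates:
            rows.append({"event_id": event_id, "mean_psi_control": np.nan,
                         "mean_psi_treated": np.nan, "delta_psi": np.nan,
                         "p_value": np.nan, "tested": False})
            continue
        res = welch_t(x, y)
        rows.append({"event_id": event_id,
                     "mean_psi_control": float(y.mean()),
                     "mean_psi_treated": float(x.mean()),
                     "delta_psi": float(x.mean() - y.mean()),
                     "p_value": res.p_value, "tested": True})
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "fdr"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    crit = out["p_value"] if use_pvalue else out["fdr"]
    out["selected"] = tested & (out["delta_psi"].abs() > delta_cutoff) & (crit < fdr_cutoff)
    return out


def direction_summary(records: pd.DataFrame,
                      event_types: dict[str, str]) -> pd.DataFrame:
    """Counts of selected events with positive vs negative dPsi per type."""
    sel = records[records["selected"]]
    types = sorted(set(event_types.values()))
    counts = {t: [0, 0] for t in types}
    for r in sel.itertuples():
        etype = event_types.get(r.event_id)
        if etype is None:
            raise ValidationError(f"event {r.event_id} has no type annotation")
        counts[etype][0 if r.delta_psi > 0 else 1] += 1
    return pd.DataFrame(
        [{"type": t, "n_positive": counts[t][0], "n_negative": counts[t][1]}
         for t in types]
    )


# -- TSV I/O ----------------------------------------------------------------

def read_junction_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_events(events: list[SpliceEvent], path: str | Path) -> None:
    """Event-definition TSV: regions encoded as 'start-end[,start-end]'."""
    with open(path, "w") as fh:
        fh.write("event_id\ttype\tgene_id\ttranscript_id\talt_region\t"
                 "len_inclusion\tlen_skipping\n")
        for e in events:
            region = ",".join(f"{a}-{b}" for a, b in e.alt_region)
            fh.write(f"{e.event_id}\t{e.type}\t{e.gene_id}\t{e.transcript_id}\t"
                     f"{region}\t{e.len_inclusion}\t{e.len_skipping}\n")


def read_events(path: str | Path) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t", comment="#")
    events = []
    for r in df.itertuples():
        region = [tuple(int(x) for x in part.split("-"))
                  for part in str(r.alt_region).split(",")]
        events.append(SpliceEvent(
            event_id=str(r.event_id), type=str(r.type), gene_id=str(r.gene_id),
            transcript_id=str(r.transcript_id), alt_region=region,
            len_inclusion=float(r.len_inclusion), len_skipping=float(r.len_skipping)))
    return events
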