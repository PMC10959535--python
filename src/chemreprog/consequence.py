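"""Protein-level consequences of splicing events and the damage statistic.

Each event is classified against its host transcript's reference protein.
The alternative form (the one differing from the annotated transcript) is
re-spliced, its ORF re-translated from the unchanged start codon, and the
event assigned exactly one category with precedence

    noncoding_region > frameshift > premature_stop > domain_loss > no_disruption

frameshift: the net coding-length change is not a multiple of 3;
premature_stop: the re-translated ORF terminates before the position the
canonical stop would occupy; domain_loss: the in-frame removed peptide
overlaps an annotated domain (or an in-frame insertion lands strictly
inside one). The splicing-damage statistic is the proportion of events in
the damaging set {frameshift, premature_stop, domain_loss}, computed
either over differentially spliced events or, per sample, over events
whose damaging isoform is present above a Psi threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedResultError, ValidationError
from .gene_models import (DomainAnnotation, GenomeSequence, TranscriptModel,
                          genomic_to_transcript, spliced_sequence, translate_orf)
from .splicing import SpliceEvent

__all__ = [
    "DAMAGING_CATEGORIES",
    "ConsequenceCall",
    "DamageReport",
    "reference_form",
    "alt_is_inclusion",
    "apply_event",
    "classify_consequence",
    "splicing_damage_differential",
    "splicing_damage_standing",
]

DAMAGING_CATEGORIES = frozenset({"frameshift", "premature_stop", "domain_loss"})
CATEGORIES = ("frameshift", "premature_stop", "domain_loss",
              "no_disruption", "noncoding_region")


@dataclass
class ConsequenceCall:
    event_id: str
    transcript_id: str
    category: str
    altered_aa_start: int | None = None
    altered_aa_end: int | None = None
    new_stop_aa: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")

    @property
    def damaging(self) -> bool:
        return self.category in DAMAGING_CATEGORIES


@dataclass
class DamageReport:
    label: str
    n_events: int
    n_damaging: int

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise UndefinedResultError(
                f"{self.label}: damage proportion undefined over zero events")

    @property
    def proportion(self) -> float:
        return self.n_damaging / self.n_events


# -- event geometry ---------------------------------------------------------

def _exon_index(t: TranscriptModel, interval: tuple[int, int]) -> int | None:
    for i, ex in enumerate(t.exons):
        if ex == tuple(interval):
            return i
    return None


def _intron_index(t: TranscriptModel, interval: tuple[int, int]) -> int | None:
    for i, intr in enumerate(t.introns):
        if intr == tuple(interval):
            return i
    return None


def reference_form(t: TranscriptModel, e: SpliceEvent) -> str:
    """Which form ('inclusion' or 'exclusion') the annotated transcript is."""
    if e.type == "SE":
        idx = _exon_index(t, e.alt_region[0])
        if idx is None or idx in (0, len(t.exons) - 1):
            raise ValidationError(
                f"{e.event_id}: SE alt region must be an internal exon of "
                f"{t.transcript_id}")
        return "inclusion"
    if e.type == "RI":
        if _intron_index(t, e.alt_region[0]) is None:
            raise ValidationError(
                f"{e.event_id}: RI alt region must be an intron of {t.transcript_id}")
        return "exclusion"
    if e.type in ("A5SS", "A3SS"):
        a, b = e.alt_region[0]
        for ex_a, ex_b in t.exons:
            # long form annotated: segment inside an exon, sharing one edge
            if (a, b) != (ex_a, ex_b) and ex_a <= a and b <= ex_b and (a == ex_a or b == ex_b):
                return "inclusion"
        for in_a, in_b in t.introns:
            # short form annotated: segment in an intron, touching an exon edge
            if in_a <= a and b <= in_b and (a == in_a or b == in_b):
                return "exclusion"
        raise ValidationError(
            f"{e.event_id}: {e.type} alt region incompatible with {t.transcript_id}")
    if e.type == "MXE":
        first, second = e.alt_region
        has_first = _exon_index(t, first) is not None
        has_second = _exon_index(t, second) is not None
        if has_first == has_second:
            raise ValidationError(
                f"{e.event_id}: MXE requires exactly one of the two exons in "
                f"{t.transcript_id}")
        return "inclusion" if has_first else "exclusion"
    raise ValidationError(f"{e.event_id}: unknown event type {e.type!r}")


def alt_is_inclusion(t: TranscriptModel, e: SpliceEvent) -> bool:
    """True when the non-reference (damage-carrying) form is the inclusion form."""
    return reference_form(t, e) == "exclusion"


def _alternative_exons(t: TranscriptModel, e: SpliceEvent
                       ) -> tuple[list[tuple[int, int]],
                                  list[tuple[int, int]], list[tuple[int, int]]]:
    """Exon list of the alternative form plus (removed, inserted) segments."""
    ref = reference_form(t, e)
    exons = list(t.exons)
    if e.type == "SE":
        seg = tuple(e.alt_region[0])
        exons.remove(seg)
        return exons, [seg], []
    if e.type == "RI":
        a, b = e.alt_region[0]
        i = _intron_index(t, (a, b))
        merged = (exons[i][0], exons[i + 1][1])
        exons[i:i + 2] = [merged]
        return exons, [], [(a, b)]
    if e.type in ("A5SS", "A3SS"):
        a, b = e.alt_region[0]
        if ref == "inclusion":  # trim the segment off its host exon
            for i, (ex_a, ex_b) in enumerate(exons):
                if ex_a <= a and b <= ex_b and (a == ex_a or b == ex_b):
                    exons[i] = (b, ex_b) if a == ex_a else (ex_a, a)
                    return exons, [(a, b)], []
        else:  # extend the adjacent exon into the intron
            for i, (ex_a, ex_b) in enumerate(exons):
                if ex_b == a:
                    exons[i] = (ex_a, b)
                    return exons, [], [(a, b)]
                if ex_a == b:
                    exons[i] = (a, ex_b)
                    return exons, [], [(a, b)]
        raise ValidationError(f"{e.event_id}: alt region incompatible with transcript")
    if e.type == "MXE":
        first, second = (tuple(r) for r in e.alt_region)
        present, absent = (first, second) if ref == "inclusion" else (second, first)
        exons.remove(present)
        exons = sorted(exons + [absent])
        return exons, [present], [absent]
    raise ValidationError(f"unknown event type {e.type!r}")


@dataclass
class AppliedForm:
    """One spliced form of an event: exon structure, mRNA, CDS offset."""

    exons: list[tuple[int, int]]
    mrna: str
    cds_offset: int | None  # None when the start codon is lost
    utr_only: bool


def apply_event(t: TranscriptModel, e: SpliceEvent, genome: GenomeSequence,
                form: str) -> AppliedForm:
    """Re-splice the transcript into the requested form of the event."""
    if form not in ("inclusion", "exclusion"):
        raise ValidationError(f"unknown form {form!r}")
    if form == reference_form(t, e):
        exons = list(t.exons)
        removed: list[tuple[int, int]] = []
        inserted: list[tuple[int, int]] = []
    else:
        exons, removed, inserted = _alternative_exons(t, e)
    mrna = spliced_sequence(t, genome, exons=exons)
    start = t.cds_start if t.strand == "+" else t.cds_end - 1
    try:
        offset = genomic_to_transcript(exons, t.strand, start)
    except Exception:
        offset = None
    coding = _coding_change(t, removed, inserted)
    return AppliedForm(exons=exons, mrna=mrna, cds_offset=offset,
                       utr_only=(coding == (0, 0) and (removed or inserted) != []))


def _coding_change(t: TranscriptModel, removed, inserted) -> tuple[int, int]:
    """(removed, inserted) base counts overlapping the genomic CDS window."""
    def ov(seg):
        a, b = seg
        return max(0, min(b, t.cds_end) - max(a, t.cds_start))
    return sum(ov(s) for s in removed), sum(ov(s) for s in inserted)


# -- classification ---------------------------------------------------------

def classify_consequence(t: TranscriptModel, e: SpliceEvent,
                         genome: GenomeSequence,
                         domains: list[DomainAnnotation],
                         nmd_rule: bool = False) -> ConsequenceCall:
    """Assign the protein-level consequence category of one event.

    ``nmd_rule``: optionally require a new stop to fall upstream of the
    last exon-exon junction of the altered form (a 50-nt-free variant of
    the NMD rule) before calling premature_stop; off by default.
    """
    ref_mrna = spliced_sequence(t, genome)
    ref_off = t.cds_offset
    ref_pep, ref_stop = translate_orf(ref_mrna, ref_off)
    if not ref_stop:
        raise ValidationError(f"{t.transcript_id}: reference ORF has no stop codon")

    alt_exons, removed, inserted = _alternative_exons(t, e)
    removed_coding, inserted_coding = _coding_change(t, removed, inserted)

    if removed_coding == 0 and inserted_coding == 0:
        return ConsequenceCall(e.event_id, t.transcript_id, "noncoding_region")

    delta = inserted_coding - removed_coding
    if delta % 3 != 0:
        aa_lo, aa_hi = _removed_aa_interval(t, removed) or (None, None)
        return ConsequenceCall(e.event_id, t.transcript_id, "frameshift",
                               altered_aa_start=aa_lo, altered_aa_end=aa_hi)

    alt_mrna = spliced_sequence(t, genome, exons=alt_exons)
    start = t.cds_start if t.strand == "+" else t.cds_end - 1
    try:
        alt_off = genomic_to_transcript(alt_exons, t.strand, start)
    except Exception:
        raise ValidationError(
            f"{e.event_id}: alternative form removes the CDS start codon") from None
    alt_pep, alt_stop = translate_orf(alt_mrna, alt_off)
    expected_len = len(ref_pep) + delta // 3
    if alt_stop and len(alt_pep) < expected_len:
        premature = True
        if nmd_rule:
            junctions = np.cumsum([b - a for a, b in
                                   (alt_exons if t.strand == "+"
                                    else list(reversed(alt_exons)))])[:-1]
            stop_pos = alt_off + 3 * len(alt_pep)
            premature = bool(len(junctions) and stop_pos < junctions[-1])
        if premature:
            return ConsequenceCall(e.event_id, t.transcript_id, "premature_stop",
                                   new_stop_aa=len(alt_pep) + 1)

    interval = _removed_aa_interval(t, removed)
    if interval is not None:
        aa_lo, aa_hi = interval
        for d in domains:
            if d.transcript_id == t.transcript_id and d.overlaps(aa_lo, aa_hi):
                return ConsequenceCall(e.event_id, t.transcript_id, "domain_loss",
                                       altered_aa_start=aa_lo, altered_aa_end=aa_hi)
    if inserted_coding:
        pos = _insertion_aa_position(t, inserted)
        if pos is not None:
            for d in domains:
                if d.transcript_id == t.transcript_id and d.start_aa <= pos < d.end_aa:
                    return ConsequenceCall(e.event_id, t.transcript_id, "domain_loss",
                                           altered_aa_start=pos, altered_aa_end=pos)
    return ConsequenceCall(e.event_id, t.transcript_id, "no_disruption")


def _removed_aa_interval(t: TranscriptModel, removed) -> tuple[int, int] | None:
    """1-based aa interval of the reference protein covered by removed coding bases."""
    positions = []
    for a, b in removed:
        ca, cb = max(a, t.cds_start), min(b, t.cds_end)
        if ca >= cb:
            continue
        p1 = t.genomic_to_transcript(ca)
        p2 = t.genomic_to_transcript(cb - 1)
        positions.extend([min(p1, p2), max(p1, p2)])
    if not positions:
        return None
    off = t.cds_offset
    lo, hi = min(positions), max(positions)
    return (lo - off) // 3 + 1, (hi - off) // 3 + 1


def _insertion_aa_position(t: TranscriptModel, inserted) -> int | None:
    """aa position (reference coords) of the codon preceding an insertion."""
    for a, b in inserted:
        if not (t.cds_start <= a and b <= t.cds_end):
            continue
        flank = a - 1 if t.strand == "+" else b
        try:
            p = t.genomic_to_transcript(flank)
        except Exception:
            continue
        return max(1, (p - t.cds_offset) // 3 + 1)
    return None


# -- damage proportion ------------------------------------------------------

def splicing_damage_differential(calls: dict[str, ConsequenceCall],
                                 records: pd.DataFrame,
                                 label: str = "comparison") -> DamageReport:
    """Damage proportion over selected differentially spliced events."""
    selected = records.loc[records["selected"], "event_id"].tolist()
    if not selected:
        raise UndefinedResultError(f"{label}: no selected events")
    missing = [ev for ev in selected if ev not in calls]
    if missing:
        raise ValidationError(f"events without consequence calls: {missing[:5]}")
    n_damaging = sum(calls[ev].damaging for ev in selected)
    return DamageReport(label=label, n_events=len(selected), n_damaging=n_damaging)


def splicing_damage_standing(calls: dict[str, ConsequenceCall],
                             psi: pd.DataFrame,
                             damaging_form_is_inclusion: dict[str, bool],
                             presence_threshold: float = 0.1) -> pd.DataFrame:
    """Per-sample damage proportion over events with coverage.

    An event counts as damaging in a sample when its category is damaging
    and the Psi of its damage-carrying isoform (psi if that isoform is the
    inclusion form, 1 - psi otherwise) is at or above the threshold.
    """
    rows = []
    for sample, sub in psi.groupby("sample", sort=True):
        covered = sub[sub["psi"].notna()]
        if covered.empty:
            raise UndefinedResultError(f"{sample}: no events with coverage")
        n_damaging = 0
        for r in covered.itertuples():
            call = calls.get(r.event_id)
            if call is None:
                raise ValidationError(f"event {r.event_id} has no consequence call")
            if not call.damaging:
                continue
            alt_psi = r.psi if damaging_form_is_inclusion[r.event_id] else 1.0 - r.psi
            if alt_psi >= presence_threshold:
                n_damaging += 1
        rows.append({"sample": sample, "n_events": len(covered),
                     "n_damaging": n_damaging,
                     "proportion": n_damaging / len(covered)})
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[ConsequenceCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "event_id": c.event_id, "transcript_id": c.transcript_id,
        "category": c.category, "altered_aa_start": c.altered_aa_start,
        "altered_aa_end": c.altered_aa_end, "new_stop_aa": c.new_stop_aa,
    } for c in calls])
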