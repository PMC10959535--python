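"""Genome sequences, transcript models, ORF translation, coordinate maps.

Coordinate convention: all in-memory intervals are 0-based half-open
``(start, end)`` on the genome; GTF I/O converts to/from the format's
1-based inclusive coordinates. Minus-strand transcripts keep their exon
lists in genomic order with a strand flag; sequences are
reverse-complemented once, at assembly, so all downstream protein-space
arithmetic runs in transcript (5'->3') space.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ParseError, RangeError, ValidationError

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "DomainAnnotation",
    "read_genome",
    "read_transcripts",
    "write_transcripts",
    "read_domains",
    "spliced_sequence",
    "translate_orf",
    "protein_to_genomic",
]

_VALID_DNA = re.compile(r"^[ACGTN]+$")


class GenomeSequence:
    """Mapping of chromosome name -> uppercase DNA string over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValidationError("genome has no sequences")
        for name, seq in sequences.items():
            if not seq:
                raise ValidationError(f"empty sequence for {name!r}")
            if not _VALID_DNA.match(seq):
                raise ValidationError(
                    f"sequence {name!r} contains characters outside A/C/G/T/N")
        self._seqs = dict(sequences)

    def __getitem__(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise ValidationError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def items(self):
        return self._seqs.items()

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise RangeError(
                f"interval [{start}, {end}) out of bounds for {chrom!r} "
                f"(length {len(seq)})")
        return seq[start:end]


def read_genome(path: str | Path) -> GenomeSequence:
    """Load a (multi-record, possibly wrapped) FASTA into memory."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(records)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by genomic start
    cds_start: int  # genomic, 0-based
    cds_end: int    # genomic, exclusive
    _cached: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in exons:
            if a >= b:
                raise ValidationError(f"{self.transcript_id}: empty exon ({a}, {b})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons
        if not (exons[0][0] <= self.cds_start < self.cds_end <= exons[-1][1]):
            raise ValidationError(f"{self.transcript_id}: CDS outside transcript span")
        for pos in (self.cds_start, self.cds_end - 1):
            if not any(a <= pos < b for a, b in exons):
                raise ValidationError(
                    f"{self.transcript_id}: CDS boundary {pos} lies in an intron")
        if self.spliced_cds_length < 3:
            raise ValidationError(f"{self.transcript_id}: spliced CDS shorter than 3 nt")

    # -- derived geometry ---------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def spliced_cds_length(self) -> int:
        return sum(max(0, min(b, self.cds_end) - max(a, self.cds_start))
                   for a, b in self.exons)

    def genomic_to_transcript(self, pos: int) -> int:
        """Transcript-space (5'->3') offset of an exonic genomic position."""
        return genomic_to_transcript(self.exons, self.strand, pos)

    @property
    def cds_offset(self) -> int:
        """Transcript-space offset of the first coding base."""
        first = self.cds_start if self.strand == "+" else self.cds_end - 1
        return self.genomic_to_transcript(first)


def genomic_to_transcript(exons: list[tuple[int, int]], strand: str, pos: int) -> int:
    off = 0
    if strand == "+":
        for a, b in exons:
            if a <= pos < b:
                return off + (pos - a)
            off += b - a
    else:
        for a, b in reversed(exons):
            if a <= pos < b:
                return off + (b - 1 - pos)
            off += b - a
    raise RangeError(f"genomic position {pos} is not exonic")


@dataclass
class DomainAnnotation:
    """A protein domain on a transcript, 1-based inclusive amino-acid coords."""

    transcript_id: str
    name: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValidationError(
                f"domain {self.name}: invalid aa interval "
                f"[{self.start_aa}, {self.end_aa}]")

    def overlaps(self, start_aa: int, end_aa: int) -> bool:
        return not (end_aa < self.start_aa or start_aa > self.end_aa)


# -- GTF I/O ----------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(text))
    if "transcript_id" not in attrs or "gene_id" not in attrs:
        raise ParseError(f"GTF line {lineno}: missing transcript_id/gene_id attribute")
    return attrs


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models (exon + CDS features) from a GTF file.

    Parse errors name the offending line number; a transcript whose CDS
    falls outside its exon union raises a validation error.
    """
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"GTF line {lineno}: expected 9 tab-separated fields, "
                                 f"got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"GTF line {lineno}: non-integer coordinates") from None
            if start_i < 1 or end_i < start_i:
                raise ParseError(f"GTF line {lineno}: invalid interval {start}-{end}")
            attrs = _parse_attributes(attr, lineno)
            tid = attrs["transcript_id"]
            rec = exons.setdefault(tid, {"gene_id": attrs["gene_id"], "chrom": chrom,
                                         "strand": strand, "exons": [], "cds": []})
            # GTF 1-based inclusive -> 0-based half-open
            rec[{"exon": "exons", "CDS": "cds"}[feature]].append((start_i - 1, end_i))

    models = []
    for tid, rec in exons.items():
        if not rec["exons"]:
            raise ValidationError(f"transcript {tid}: no exon features")
        if not rec["cds"]:
            raise ValidationError(f"transcript {tid}: no CDS features")
        cds_start = min(a for a, _ in rec["cds"])
        cds_end = max(b for _, b in rec["cds"])
        models.append(TranscriptModel(
            transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
            strand=rec["strand"], exons=rec["exons"],
            cds_start=cds_start, cds_end=cds_end))
    return models


def write_transcripts(models: list[TranscriptModel], path: str | Path,
                      source: str = "chemreprog") -> None:
    with open(path, "w") as fh:
        for t in models:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for a, b in t.exons:
                fh.write(f"{t.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n")
            for a, b in t.exons:
                ca, cb = max(a, t.cds_start), min(b, t.cds_end)
                if ca < cb:
                    fh.write(f"{t.chrom}\t{source}\tCDS\t{ca + 1}\t{cb}\t.\t{t.strand}\t0\t{attrs}\n")


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    """Read protein-domain intervals from a BED-dialect file.

    Columns: transcript_id, start_aa-1, end_aa, name — i.e. standard BED
    half-open numerics, with the chrom column carrying the transcript id
    and coordinates in amino acids.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"domain BED line {lineno}: expected >=4 columns")
            tid, start, end, name = fields[:4]
            try:
                start_aa, end_aa = int(start) + 1, int(end)
            except ValueError:
                raise ParseError(f"domain BED line {lineno}: non-integer coordinates") from None
            out.append(DomainAnnotation(tid, name, start_aa, end_aa))
    return out


def write_domains(domains: list[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.transcript_id}\t{d.start_aa - 1}\t{d.end_aa}\t{d.name}\n")


# -- sequence assembly and translation --------------------------------------

def spliced_sequence(t: TranscriptModel, genome: GenomeSequence,
                     exons: list[tuple[int, int]] | None = None) -> str:
    """mRNA of the transcript: exon concatenation, reverse-complemented on '-'."""
    parts = [genome.fetch(t.chrom, a, b) for a, b in (exons if exons is not None else t.exons)]
    seq = "".join(parts)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate_orf(mrna: str, cds_offset: int) -> tuple[str, bool]:
    """Translate from ``cds_offset`` to the first in-frame stop (or the end).

    Returns (peptide, stop_reached). Codons containing N translate to 'X'
    and never count as stops.
    """
    if not (0 <= cds_offset < len(mrna)):
        raise RangeError(f"CDS offset {cds_offset} outside mRNA of length {len(mrna)}")
    coding = mrna[cds_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    translated = str(Seq(coding).translate())
    stop_at = translated.find("*")
    if stop_at >= 0:
        return translated[:stop_at], True
    return translated, False


def protein_to_genomic(t: TranscriptModel, aa_interval: tuple[int, int]) -> list[tuple[int, int]]:
    """Genomic interval(s) coding for a 1-based inclusive aa interval.

    The returned intervals (genomic order, 0-based half-open) cover exactly
    3 x (aa span) coding bases, split across exons where needed.
    """
    start_aa, end_aa = aa_interval
    if start_aa < 1 or end_aa < start_aa:
        raise RangeError(f"invalid aa interval [{start_aa}, {end_aa}]")
    cds_len = t.spliced_cds_length
    if end_aa * 3 > cds_len:
        raise RangeError(
            f"aa interval end {end_aa} exceeds protein length {cds_len // 3}")
    lo = t.cds_offset + (start_aa - 1) * 3  # transcript coords
    hi = t.cds_offset + end_aa * 3

    # walk exons in transcript (5'->3') order
    ordered = t.exons if t.strand == "+" else list(reversed(t.exons))
    intervals: list[tuple[int, int]] = []
    off = 0
    for a, b in ordered:
        length = b - a
        seg_lo, seg_hi = max(lo, off), min(hi, off + length)
        if seg_lo < seg_hi:
            if t.strand == "+":
                intervals.append((a + (seg_lo - off), a + (seg_hi - off)))
            else:
                intervals.append((b - (seg_hi - off), b - (seg_lo - off)))
        off += length
    return sorted(intervals)
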