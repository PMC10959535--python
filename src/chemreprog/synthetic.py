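"""Synthetic multi-omics data with known ground truth.

Every pipeline stage is exercised on data this module generates: a toy
genome with multi-exon genes on both strands carrying one engineered
splicing event each (all five event types, consequence category realized
by construction), binomially sampled junction counts around group-specific
true Psi, negative-binomial gene counts with designed fold changes,
logistic-normal methylation with state-structured DMPs, and expression
built by inverting a linear transcriptomic clock.

One global seed expands to independent per-stream child seeds so stages
stay reproducible when another stage's parameters change.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clocks import ClockModel, write_clock
from .errors import ValidationError
from .gene_models import (DomainAnnotation, GenomeSequence, TranscriptModel,
                          write_domains, write_genome, write_transcripts)
from .splicing import SpliceEvent, write_events

__all__ = [
    "child_seed",
    "SyntheticAnnotation",
    "simulate_genome_annotation",
    "simulate_splicing_counts",
    "simulate_expression",
    "simulate_methylation",
    "make_synthetic_clock",
    "simulate_clock_study",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))
_NONSTOP = np.array([a + b + c
                     for a in "ACGT" for b in "ACGT" for c in "ACGT"
                     if a + b + c not in _STOPS])
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_CATEGORY_MIX = {
    "frameshift": 0.2, "premature_stop": 0.2, "domain_loss": 0.2,
    "no_disruption": 0.2, "noncoding_region": 0.2,
}

# event types able to realize each category by construction
_COMPATIBLE_TYPES = {
    "frameshift": ["SE", "RI", "A5SS", "A3SS", "MXE"],
    "premature_stop": ["RI", "MXE"],
    "domain_loss": ["SE", "A5SS", "A3SS", "MXE"],
    "no_disruption": ["SE", "RI", "A5SS", "A3SS", "MXE"],
    "noncoding_region": ["SE", "RI"],
}


def child_seed(seed: int, stream: str) -> int:
    """Deterministic per-stream child seed below 2**31."""
    return (int(seed) * 100003 + zlib.crc32(stream.encode())) % (2**31 - 1)


def _rand_dna(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))

def _rand_codons(rng, n: int) -> str:
    return "".join(rng.choice(_NONSTOP, size=n))

def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# -- genome + annotation ----------------------------------------------------

@dataclass
class SyntheticAnnotation:
    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    domains: list[DomainAnnotation]
    events: list[SpliceEvent]
    truth: pd.DataFrame  # event_id, gene_id, transcript_id, type, category

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "domains": outdir / "domains.bed",
            "events": outdir / "events.tsv",
            "truth": outdir / "truth_events.tsv",
        }
        write_genome(self.genome, paths["genome"])
        write_transcripts(self.transcripts, paths["gtf"])
        write_domains(self.domains, paths["domains"])
        write_events(self.events, paths["events"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _allocate(mix: dict[str, float], n: int) -> list[str]:
    """Largest-remainder allocation so the requested mix is realized exactly."""
    total = sum(mix.values())
    if total <= 0:
        raise ValidationError("category mix must have positive total weight")
    quotas = {c: n * w / total for c, w in mix.items()}
    counts = {c: int(q) for c, q in quotas.items()}
    remainder = n - sum(counts.values())
    for c in sorted(mix, key=lambda c: (-(quotas[c] - counts[c]), c))[:remainder]:
        counts[c] += 1
    out = []
    for c in sorted(counts):
        out.extend([c] * counts[c])
    return out


def simulate_genome_annotation(seed: int, n_genes: int = 40,
                               category_mix: dict[str, float] | None = None
                               ) -> SyntheticAnnotation:
    """Toy genome: one gene per chromosome, one engineered event per gene.

    Genes alternate strand. Every gene follows a fixed skeleton (5'UTR,
    three coding exons around a designed internal exon, stop, a split
    3'UTR); the designed pieces realize the assigned (type, category)
    pair: exon lengths mod 3, embedded in-frame stops, domain placement.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    rng = np.random.default_rng(child_seed(seed, "annotation"))
    mix = dict(category_mix or DEFAULT_CATEGORY_MIX)
    unknown = set(mix) - set(_COMPATIBLE_TYPES)
    if unknown:
        raise ValidationError(f"unknown categories in mix: {sorted(unknown)}")
    categories = _allocate(mix, n_genes)
    type_cursor = {c: 0 for c in _COMPATIBLE_TYPES}

    genome: dict[str, str] = {}
    transcripts, domains, events, truth_rows = [], [], [], []
    for gi, category in enumerate(categories):
        types = _COMPATIBLE_TYPES[category]
        etype = types[type_cursor[category] % len(types)]
        type_cursor[category] += 1
        gid = f"gene{gi:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        chrom = f"chr_{gid}"
        seq, transcript, gene_domains, event = _build_gene(
            rng, gid, chrom, strand, etype, category)
        genome[chrom] = seq
        transcripts.append(transcript)
        domains.extend(gene_domains)
        events.append(event)
        truth_rows.append({"event_id": event.event_id, "gene_id": gid,
                           "transcript_id": transcript.transcript_id,
                           "type": etype, "category": category})
    return SyntheticAnnotation(
        genome=GenomeSequence(genome), transcripts=transcripts, domains=domains,
        events=events, truth=pd.DataFrame(truth_rows))


def _build_gene(rng, gid: str, chrom: str, strand: str, etype: str,
                category: str):
    tid = f"{gid}.t1"
    event_id = f"{gid}.ev"
    spacer = 50
    utr5_len, utr3a_len, utr3b_len, utr3c_len = 12, 15, 24, 18
    c0, c2 = 30, 60
    len_e1 = 100 if (etype == "SE" and category == "frameshift") else 99
    c_last = 30 + ((-(c0 + len_e1 + c2)) % 3)
    total_cds = c0 + len_e1 + c2 + c_last

    cds = _rand_codons(rng, total_cds // 3)
    e0c, e1 = cds[:c0], cds[c0:c0 + len_e1]
    e2, e3c = cds[c0 + len_e1:c0 + len_e1 + c2], cds[c0 + len_e1 + c2:]

    def designed_insert(n_codons: int, with_stop: bool, extra_base: bool) -> str:
        raw = _rand_codons(rng, n_codons)
        codons = [raw[i * 3:(i + 1) * 3] for i in range(n_codons)]
        if with_stop:
            codons[10] = "TAA"  # in frame: insertion point is codon-aligned
        s = "".join(codons)
        return s + "A" if extra_base else s

    # introns; I0 and the MXE pocket in I1 are the designed ones
    if etype == "RI" and category != "noncoding_region":
        i0 = designed_insert(30, with_stop=(category == "premature_stop"),
                             extra_base=(category == "frameshift"))
    else:
        i0 = _rand_dna(rng, int(rng.integers(60, 120)))
    if etype == "MXE":
        n_x = 33
        mxe_x = designed_insert(n_x, with_stop=(category == "premature_stop"),
                                extra_base=(category == "frameshift"))
        i1 = _rand_dna(rng, 60) + mxe_x + _rand_dna(rng, 60)
        x_off_in_i1 = 60
    else:
        mxe_x = None
        i1 = _rand_dna(rng, int(rng.integers(60, 120)))
    i2, i3 = (_rand_dna(rng, int(rng.integers(60, 120))) for _ in range(2))
    i4 = _rand_dna(rng, int(rng.integers(60, 120)))

    blocks = [
        ("exon", _rand_dna(rng, utr5_len) + e0c),
        ("intron", i0),
        ("exon", e1),
        ("intron", i1),
        ("exon", e2),
        ("intron", i2),
        ("exon", e3c + "TAA" + _rand_dna(rng, utr3a_len)),
        ("intron", i3),
        ("exon", _rand_dna(rng, utr3b_len)),
        ("intron", i4),
        ("exon", _rand_dna(rng, utr3c_len)),
    ]
    forward = _rand_dna(rng, spacer) + "".join(s for _, s in blocks) + _rand_dna(rng, spacer)
    offsets, pos = [], spacer
    for kind, s in blocks:
        offsets.append((kind, pos, pos + len(s)))
        pos += len(s)
    exon_iv = [(a, b) for kind, a, b in offsets if kind == "exon"]
    intron_iv = [(a, b) for kind, a, b in offsets if kind == "intron"]
    cds_start_f = exon_iv[0][0] + utr5_len
    cds_end_f = exon_iv[3][0] + c_last + 3  # stop codon included

    # event alternative region in forward space
    seg = 7 if category == "frameshift" else 9
    if etype == "SE":
        region = [exon_iv[1] if category != "noncoding_region" else exon_iv[4]]
    elif etype == "RI":
        region = [intron_iv[0] if category != "noncoding_region" else intron_iv[4]]
    elif etype == "A5SS":
        a, b = exon_iv[1]
        region = [(b - seg, b)]
    elif etype == "A3SS":
        a, b = exon_iv[2]
        region = [(a, a + seg)]
    else:  # MXE: [inclusion exon, alternative exon]
        xa = intron_iv[1][0] + x_off_in_i1
        region = [exon_iv[1], (xa, xa + len(mxe_x))]

    # domains (1-based inclusive aa); every gene carries a decoy
    gene_domains = [DomainAnnotation(tid, "decoy", 2, 4)]
    if category == "domain_loss":
        aa = {"SE": (c0 // 3 + 1, (c0 + len_e1) // 3),
              "A5SS": ((c0 + len_e1 - seg) // 3 + 1, (c0 + len_e1) // 3),
              "A3SS": ((c0 + len_e1) // 3 + 1, (c0 + len_e1 + seg) // 3),
              "MXE": (c0 // 3 + 1, (c0 + len_e1) // 3)}[etype]
        gene_domains.append(DomainAnnotation(tid, "designed", aa[0], aa[1]))

    if strand == "-":
        total = len(forward)
        forward = _revcomp(forward)
        exon_iv = sorted((total - b, total - a) for a, b in exon_iv)
        region = [(total - b, total - a) for a, b in region]
        cds_start_f, cds_end_f = total - cds_end_f, total - cds_start_f

    transcript = TranscriptModel(
        transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
        exons=exon_iv, cds_start=cds_start_f, cds_end=cds_end_f)
    len_inc, len_skip = (2.0, 2.0) if etype == "MXE" else (2.0, 1.0)
    event = SpliceEvent(event_id=event_id, type=etype, gene_id=gid,
                        transcript_id=tid, alt_region=region,
                        len_inclusion=len_inc, len_skipping=len_skip)
    return forward, transcript, gene_domains, event


# -- junction counts --------------------------------------------------------

def simulate_splicing_counts(events: list[SpliceEvent],
                             psi_control, delta,
                             n_reps: int = 4, depth: int = 200,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial junction counts around group-specific true Psi.

    ``psi_control`` / ``delta`` are floats or per-event-id dicts; treated
    Psi is psi + delta. Inclusion reads are Binomial(depth, p*) with
    p* = psi l_I / (psi l_I + (1 - psi) l_S); skipping reads make up the
    rest. Returns (long counts table, truth table).
    """
    rng = np.random.default_rng(child_seed(seed, "splicing"))

    def lookup(x, eid):
        return float(x[eid]) if isinstance(x, dict) else float(x)

    samples = [("control", f"ctrl_{i + 1}") for i in range(n_reps)] + \
              [("treated", f"trt_{i + 1}") for i in range(n_reps)]
    rows, truth = [], []
    for e in events:
        psi0 = lookup(psi_control, e.event_id)
        d = lookup(delta, e.event_id)
        psi1 = psi0 + d
        for value, name in ((psi0, "control"), (psi1, "treated")):
            if not (0.0 <= value <= 1.0):
                raise ValidationError(
                    f"{e.event_id}: {name} psi {value} outside [0, 1]")
        for group, sample in samples:
            psi = psi1 if group == "treated" else psi0
            p_star = (psi * e.len_inclusion /
                      (psi * e.len_inclusion + (1.0 - psi) * e.len_skipping))
            inc = int(rng.binomial(depth, p_star))
            rows.append({"event_id": e.event_id, "type": e.type,
                         "sample": sample, "group": group,
                         "inclusion_count": inc, "skipping_count": depth - inc,
                         "len_inclusion": e.len_inclusion,
                         "len_skipping": e.len_skipping})
        truth.append({"event_id": e.event_id, "psi_control": psi0,
                      "psi_treated": psi1, "delta_psi": d})
    return pd.DataFrame(rows), pd.DataFrame(truth)


# -- gene counts ------------------------------------------------------------

def simulate_expression(n_genes: int = 1000, n_per_group: int = 4,
                        frac_de: float = 0.1, lfc_magnitude: float = 2.0,
                        dispersion: float = 0.1, seed: int = 0,
                        base_mean_range: tuple[float, float] = (20.0, 500.0),
                        size_factor_sd: float = 0.3
                        ) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Negative-binomial counts for a two-group design with known DE genes.

    DE genes (fraction ``frac_de``) are shifted by +/-``lfc_magnitude``
    log2 units in the treated group; per-sample library factors are drawn
    log-normal and recorded in the truth table. Returns
    (counts, sample->group map, truth with is_de/true_lfc/size factors).
    """
    rng = np.random.default_rng(child_seed(seed, "expression"))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"ctrl_{i + 1}" for i in range(n_per_group)] + \
              [f"trt_{i + 1}" for i in range(n_per_group)]
    groups = {s: ("control" if s.startswith("ctrl") else "treated") for s in samples}

    base = rng.uniform(np.log(base_mean_range[0]), np.log(base_mean_range[1]), n_genes)
    base = np.exp(base)
    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    true_lfc = np.zeros(n_genes)
    true_lfc[de_idx] = lfc_magnitude * rng.choice([-1.0, 1.0], size=n_de)
    size_factors = np.exp(rng.normal(0.0, size_factor_sd, len(samples)))

    r = 1.0 / dispersion
    counts = np.empty((n_genes, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        mu = base * size_factors[j]
        if groups[s] == "treated":
            mu = mu * np.power(2.0, true_lfc)
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = pd.DataFrame({"gene": genes, "base_mean": base,
                          "is_de": true_lfc != 0.0, "true_lfc": true_lfc})
    truth.attrs["size_factors"] = pd.Series(size_factors, index=samples)
    return counts_df, groups, truth


# -- methylation ------------------------------------------------------------

_STATE_BASELINE_M = {"enhancer": -1.0, "promoter": -3.0,
                     "heterochromatin": 3.0, "quiescent": 0.0}


def simulate_methylation(n_probes: int = 1000,
                         states: tuple[str, ...] = ("enhancer", "promoter",
                                                    "heterochromatin", "quiescent"),
                         frac_dmp: float = 0.05, delta_m: float = 2.0,
                         n_per_group: int = 5, noise_sd: float = 0.3,
                         target_state: str = "enhancer",
                         target_frac: float = 0.8,
                         direction: str = "hypo", seed: int = 0
                         ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Beta-distributed methylation with state-structured true DMPs.

    Per-probe M baselines are state-specific; true DMPs (fraction
    ``frac_dmp``) shift the treated group by ``delta_m`` on the M scale
    (sign per ``direction``) and are placed in ``target_state`` with
    probability ``target_frac``. Betas are the logistic transform of
    noisy M values, hence always in [0, 1].
    """
    if not 0.0 <= frac_dmp <= 1.0:
        raise ValidationError("frac_dmp must lie in [0, 1]")
    if direction not in ("hyper", "hypo"):
        raise ValidationError("direction must be 'hyper' or 'hypo'")
    rng = np.random.default_rng(child_seed(seed, "methylation"))
    probes = [f"cg{i:06d}" for i in range(n_probes)]
    state_assign = rng.choice(list(states), size=n_probes)
    baseline = np.array([_STATE_BASELINE_M.get(s, 0.0) for s in state_assign])
    baseline = baseline + rng.normal(0.0, 0.5, n_probes)

    n_dmp = int(round(frac_dmp * n_probes))
    in_target = np.flatnonzero(state_assign == target_state)
    others = np.flatnonzero(state_assign != target_state)
    n_from_target = min(int(round(target_frac * n_dmp)), len(in_target))
    dmp_idx = np.concatenate([
        rng.choice(in_target, size=n_from_target, replace=False),
        rng.choice(others, size=n_dmp - n_from_target, replace=False),
    ]).astype(int) if n_dmp else np.empty(0, dtype=int)
    shift = np.zeros(n_probes)
    shift[dmp_idx] = -delta_m if direction == "hypo" else delta_m

    samples = [f"ctrl_{i + 1}" for i in range(n_per_group)] + \
              [f"trt_{i + 1}" for i in range(n_per_group)]
    m = np.empty((n_probes, len(samples)))
    for j, s in enumerate(samples):
        mu = baseline + (shift if s.startswith("trt") else 0.0)
        m[:, j] = mu + rng.normal(0.0, noise_sd, n_probes)
    beta = pd.DataFrame(2.0 ** m / (2.0 ** m + 1.0), index=probes, columns=samples)
    state_map = pd.Series(state_assign, index=probes, name="state")
    truth = pd.DataFrame({"probe": probes, "state": state_assign,
                          "is_dmp": shift != 0.0, "true_delta_m": shift})
    return beta, state_map, truth


# -- clock study ------------------------------------------------------------

def make_synthetic_clock(n_genes: int = 50, intercept: float = 12.0,
                         weight_scale: float = 0.05, seed: int = 0) -> ClockModel:
    """A linear clock with alternating-sign weights and unit training sd."""
    rng = np.random.default_rng(child_seed(seed, "clock_model"))
    genes = pd.DataFrame({
        "weight": weight_scale * np.where(np.arange(n_genes) % 2 == 0, 1.0, -1.0),
        # means sit high enough on the log2 scale that inverting the clock
        # for extreme ages never drives expression below zero
        "training_mean": rng.uniform(8.0, 12.0, n_genes),
        "training_sd": np.ones(n_genes),
    }, index=[f"clk{i:04d}" for i in range(n_genes)])
    genes["imputation_value"] = genes["training_mean"]
    return ClockModel(intercept=intercept, genes=genes)


def simulate_clock_study(clock: ClockModel, true_ages: dict[str, float],
                         noise_sd: float = 1.0,
                         treatment_shift: dict[str, float] | None = None,
                         seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression whose noiseless clock readout equals the target ages.

    Inverts the clock (z_g proportional to w_g) so that on noiseless data
    apply_clock returns exactly ``true_age - shift`` per sample; Gaussian
    noise of sd ``noise_sd`` is then added on the log2 scale. Returns
    (gene x sample expression matrix, truth table).
    """
    rng = np.random.default_rng(child_seed(seed, "clock_study"))
    g = clock.genes
    w = g["weight"].to_numpy()
    ssq = float((w ** 2).sum())
    if ssq == 0:
        raise ValidationError("clock has all-zero weights")
    samples = sorted(true_ages)
    shifts = treatment_shift or {}
    cols, rows = {}, []
    for s in samples:
        target = float(true_ages[s]) - float(shifts.get(s, 0.0))
        z = w * (target - clock.intercept) / ssq
        x = g["training_mean"].to_numpy() + g["training_sd"].to_numpy() * z
        x_noisy = x + rng.normal(0.0, noise_sd, len(w))
        cols[s] = np.maximum(2.0 ** x_noisy - 1.0, 0.0)
        rows.append({"sample": s, "true_age": float(true_ages[s]),
                     "shift": float(shifts.get(s, 0.0)), "target_age": target})
    expr = pd.DataFrame(cols, index=g.index)
    return expr, pd.DataFrame(rows).set_index("sample")
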