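"""End-to-end synthetic-study runner: configuration, stages, manifest.

``run_pipeline`` executes the stages in dependency order (simulate ->
Psi -> differential splicing -> consequence -> damage -> DE -> signatures
-> GSEA association -> signature correlation -> clock -> methylation ->
state enrichment), writes every stage's outputs as headered TSVs under
the output directory, and records a manifest (tool version, config hash,
per-file sha256, seed provenance, documented method substitutions). A
re-run against an existing manifest skips stages whose outputs are
up to date by checksum and reloads them from disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import clocks, consequence, enrichment, expression, methylation, splicing
from .errors import ValidationError
from .gene_models import read_domains, read_genome, read_transcripts
from .synthetic import (child_seed, make_synthetic_clock,
                        simulate_clock_study, simulate_expression,
                        simulate_genome_annotation, simulate_methylation,
                        simulate_splicing_counts)

log = logging.getLogger("chemreprog")

DEVIATIONS = [
    "differential splicing: Welch t on replicate Psi replaces rMATS's hierarchical model",
    "differential expression: Welch t on log2 RLE-normalized counts replaces edgeR's NB fit",
    "differential methylation: ordinary per-probe tests replace limma moderation",
    "post-hoc contrasts: pairwise Welch t with BH replaces studentized-range Tukey",
]


@dataclass
class RunConfig:
    """Thresholds, sizes, seeds and mode switches for one pipeline run."""

    seed: int = 1
    # splicing
    n_genes_annotation: int = 40
    splice_n_reps: int = 4
    splice_depth: int = 200
    psi_control: float = 0.5
    delta_magnitude: float = 0.3
    min_coverage: int = 10
    delta_psi_cutoff: float = 0.1
    splice_fdr_cutoff: float = 0.05
    splice_use_pvalue: bool = False
    presence_threshold: float = 0.1
    # expression
    expr_n_genes: int = 1000
    expr_n_per_group: int = 4
    expr_frac_de: float = 0.1
    expr_lfc: float = 2.0
    expr_dispersion: float = 0.1
    filter_min_reads: int = 5
    filter_min_fraction: float = 0.2
    # GSEA
    gsea_n_perm: int = 5000
    gsea_fdr_cutoff: float = 0.1
    gsea_min_size: int = 5
    signature_n: int = 500
    signature_adj_cutoff: float = 0.05
    correlation_top_n: int = 650
    # clock
    clock_n_genes: int = 50
    clock_intercept: float = 12.0
    clock_noise_sd: float = 1.0
    clock_shift: float = -5.0
    clock_n_per_group: int = 4
    # methylation
    meth_n_probes: int = 1000
    meth_n_per_group: int = 5
    meth_frac_dmp: float = 0.05
    meth_delta_m: float = 2.0
    dmp_lfc_cutoff: float = 1.0
    dmp_fdr_cutoff: float = 0.05

    def __post_init__(self) -> None:
        positive = ["delta_psi_cutoff", "splice_fdr_cutoff", "gsea_fdr_cutoff",
                    "dmp_lfc_cutoff", "dmp_fdr_cutoff", "filter_min_reads",
                    "filter_min_fraction", "presence_threshold"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        if not Path(path).exists():
            raise ValidationError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str,
              index: bool = False, index_label: str | None = None) -> None:
    """TSV with a '#' metadata header carrying tool version and config hash."""
    with open(path, "w") as fh:
        fh.write(f"#chemreprog {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def _read_indexed(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on synthetic inputs; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    seed = config.seed
    for line in DEVIATIONS:
        log.info("method substitution: %s", line)

    manifest_path = outdir / "manifest.json"
    previous: dict = {}
    if manifest_path.exists():
        try:
            prev = json.loads(manifest_path.read_text())
            if prev.get("config_hash") == cfg_hash:
                previous = prev.get("stages", {})
        except json.JSONDecodeError:
            previous = {}
    stages: dict[str, dict] = {}

    def stage(name: str, filenames: list[str], compute, load):
        paths = [outdir / f for f in filenames]
        recorded = previous.get(name, {}).get("files", {})
        if recorded and all(p.exists() for p in paths) and \
                {p.name: _sha256(p) for p in paths} == recorded:
            log.info("stage %s: up to date, skipping", name)
            result = load(paths)
            stages[name] = {"files": recorded, "skipped": True}
            return result
        log.info("stage %s: running", name)
        result = compute(paths)
        stages[name] = {"files": {p.name: _sha256(p) for p in paths},
                        "skipped": False}
        return result

    # -- annotation + events ------------------------------------------------
    def compute_annotation(paths):
        ann = simulate_genome_annotation(seed, n_genes=config.n_genes_annotation)
        ann.write(outdir)
        return ann

    def load_annotation(paths):
        from .splicing import read_events
        from .synthetic import SyntheticAnnotation
        return SyntheticAnnotation(
            genome=read_genome(outdir / "genome.fa"),
            transcripts=read_transcripts(outdir / "annotation.gtf"),
            domains=read_domains(outdir / "domains.bed"),
            events=read_events(outdir / "events.tsv"),
            truth=pd.read_csv(outdir / "truth_events.tsv", sep="\t"))

    ann = stage("annotation",
                ["genome.fa", "annotation.gtf", "domains.bed", "events.tsv",
                 "truth_events.tsv"],
                compute_annotation, load_annotation)
    transcripts = {t.transcript_id: t for t in ann.transcripts}
    event_types = {e.event_id: e.type for e in ann.events}

    # -- junction counts + Psi ----------------------------------------------
    def compute_counts(paths):
        deltas = {}
        sign = 1.0
        for e in ann.events:
            if e.type == "RI":
                deltas[e.event_id] = -config.delta_magnitude
            else:
                deltas[e.event_id] = sign * config.delta_magnitude
                sign = -sign
        counts, truth = simulate_splicing_counts(
            ann.events, psi_control=config.psi_control, delta=deltas,
            n_reps=config.splice_n_reps, depth=config.splice_depth, seed=seed)
        write_tsv(counts, paths[0], cfg_hash)
        write_tsv(truth, paths[1], cfg_hash)
        return counts

    counts = stage("junction_counts", ["junction_counts.tsv", "truth_psi.tsv"],
                   compute_counts,
                   lambda paths: pd.read_csv(paths[0], sep="\t", comment="#"))
    splice_groups = dict(zip(counts["sample"], counts["group"]))

    def compute_psi(paths):
        psi = splicing.psi_matrix(counts, min_coverage=config.min_coverage)
        write_tsv(psi, paths[0], cfg_hash)
        return psi

    psi = stage("psi", ["psi_matrix.tsv"], compute_psi,
                lambda paths: pd.read_csv(paths[0], sep="\t", comment="#"))

    def compute_diff(paths):
        rec = splicing.differential_splicing(
            psi, splice_groups, control="control", treated="treated",
            delta_cutoff=config.delta_psi_cutoff,
            fdr_cutoff=config.splice_fdr_cutoff,
            use_pvalue=config.splice_use_pvalue)
        write_tsv(rec, paths[0], cfg_hash)
        direction = splicing.direction_summary(rec, event_types)
        write_tsv(direction, paths[1], cfg_hash)
        return rec

    records = stage("diff_splice", ["diff_splice.tsv", "direction_summary.tsv"],
                    compute_diff,
                    lambda paths: pd.read_csv(paths[0], sep="\t", comment="#"))

    # -- consequences + damage ----------------------------------------------
    def compute_consequence(paths):
        calls = [consequence.classify_consequence(
                     transcripts[e.transcript_id], e, ann.genome, ann.domains)
                 for e in ann.events]
        write_tsv(consequence.calls_to_frame(calls), paths[0], cfg_hash)
        return calls

    def load_consequence(paths):
        df = pd.read_csv(paths[0], sep="\t", comment="#")
        return [consequence.ConsequenceCall(
                    event_id=r.event_id, transcript_id=r.transcript_id,
                    category=r.category)
                for r in df.itertuples()]

    calls = stage("consequence", ["consequence_calls.tsv"],
                  compute_consequence, load_consequence)
    call_map = {c.event_id: c for c in calls}
    alt_inclusion = {e.event_id: consequence.alt_is_inclusion(
        transcripts[e.transcript_id], e) for e in ann.events}

    def compute_damage(paths):
        diff = consequence.splicing_damage_differential(
            call_map, records, label="treated_vs_control")
        diff_df = pd.DataFrame([{"label": diff.label, "n_events": diff.n_events,
                                 "n_damaging": diff.n_damaging,
                                 "proportion": diff.proportion}])
        write_tsv(diff_df, paths[0], cfg_hash)
        standing = consequence.splicing_damage_standing(
            call_map, psi, alt_inclusion,
            presence_threshold=config.presence_threshold)
        write_tsv(standing, paths[1], cfg_hash)
        return diff_df

    stage("damage", ["damage_differential.tsv", "damage_standing.tsv"],
          compute_damage,
          lambda paths: pd.read_csv(paths[0], sep="\t", comment="#"))

    # -- expression + DE ----------------------------------------------------
    def compute_de(paths):
        raw, groups, truth = simulate_expression(
            n_genes=config.expr_n_genes, n_per_group=config.expr_n_per_group,
            frac_de=config.expr_frac_de, lfc_magnitude=config.expr_lfc,
            dispersion=config.expr_dispersion, seed=seed)
        write_tsv(raw, outdir / "counts.tsv", cfg_hash, index=True,
                  index_label="gene")
        write_tsv(truth, outdir / "truth_expression.tsv", cfg_hash)
        filtered = expression.filter_genes(raw, config.filter_min_reads,
                                           config.filter_min_fraction)
        normalized, factors = expression.rle_normalize(filtered)
        write_tsv(factors.to_frame(), outdir / "size_factors.tsv", cfg_hash,
                  index=True, index_label="sample")
        de = expression.differential_expression(
            normalized, groups, control="control", treated="treated")
        write_tsv(de, paths[0], cfg_hash, index=True, index_label="gene")
        return de

    de = stage("differential_expression",
               ["de.tsv", "counts.tsv", "truth_expression.tsv", "size_factors.tsv"],
               compute_de, lambda paths: _read_indexed(paths[0]))

    # -- signatures + GSEA association + correlation ------------------------
    def compute_assoc(paths):
        up, down = enrichment.build_signature(
            de, n=config.signature_n, adj_cutoff=config.signature_adj_cutoff,
            split=True)
        rng_genes = sorted(de.index[:: max(1, len(de) // 50)][:50])
        sigs = {"self_up": up, "self_down": down, "random_set": set(rng_genes)}
        enrichment.write_gmt(sigs, outdir / "signatures.gmt")
        assoc = enrichment.signature_association(
            {"treated_vs_control": de}, sigs, n_perm=config.gsea_n_perm,
            seed=child_seed(seed, "gsea"), min_size=config.gsea_min_size)
        write_tsv(assoc, paths[0], cfg_hash)
        return assoc

    stage("signature_association", ["signature_association.tsv", "signatures.gmt"],
          compute_assoc, lambda paths: pd.read_csv(paths[0], sep="\t", comment="#"))

    def compute_corr(paths):
        raw2, groups2, _ = simulate_expression(
            n_genes=config.expr_n_genes, n_per_group=config.expr_n_per_group,
            frac_de=config.expr_frac_de, lfc_magnitude=config.expr_lfc,
            dispersion=config.expr_dispersion, seed=seed + 1)
        filtered2 = expression.filter_genes(raw2, config.filter_min_reads,
                                            config.filter_min_fraction)
        normalized2, _ = expression.rle_normalize(filtered2)
        de2 = expression.differential_expression(
            normalized2, groups2, control="control", treated="treated")
        rho_self = enrichment.signature_correlation(de, de, n=config.correlation_top_n)
        rho_indep = enrichment.signature_correlation(de, de2,
                                                     n=config.correlation_top_n)
        out = pd.DataFrame([
            {"pair": "replicate_vs_self", "rho": rho_self},
            {"pair": "replicate_vs_independent", "rho": rho_indep},
        ])
        write_tsv(out, paths[0], cfg_hash)
        return out

    stage("signature_correlation", ["signature_correlation.tsv"],
          compute_corr, lambda paths: pd.read_csv(paths[0], sep="\t", comment="#"))

    # -- transcriptomic clock ------------------------------------------------
    def compute_clock(paths):
        clock = make_synthetic_clock(n_genes=config.clock_n_genes,
                                     intercept=config.clock_intercept, seed=seed)
        clocks.write_clock(clock, outdir / "clock_model.tsv")
        n = config.clock_n_per_group
        ages, shifts, groups = {}, {}, {}
        for age_label, age in (("young", 4.0), ("old", 20.0)):
            for cond in ("control", "treated"):
                for i in range(n):
                    s = f"{age_label}_{cond}_{i + 1}"
                    ages[s] = age
                    groups[s] = f"{age_label}_{cond}"
                    if cond == "treated":
                        # clock_shift is the tAge change; the study subtracts it
                        shifts[s] = -config.clock_shift
        expr, truth = simulate_clock_study(
            clock, ages, noise_sd=config.clock_noise_sd,
            treatment_shift=shifts, seed=seed)
        preds = clocks.apply_clock(expr, clock)
        write_tsv(preds, paths[0], cfg_hash, index=True, index_label="sample")
        comp = clocks.compare_tages(preds, groups,
                                    pairs=[("young_treated", "young_control"),
                                           ("old_treated", "old_control")])
        write_tsv(comp, paths[1], cfg_hash)
        write_tsv(truth, outdir / "truth_clock.tsv", cfg_hash, index=True,
                  index_label="sample")
        return comp

    stage("clock", ["tage_predictions.tsv", "tage_comparisons.tsv",
                    "clock_model.tsv", "truth_clock.tsv"],
          compute_clock, lambda paths: pd.read_csv(paths[1], sep="\t", comment="#"))

    # -- methylation ---------------------------------------------------------
    def compute_methylation(paths):
        beta, state_map, truth = simulate_methylation(
            n_probes=config.meth_n_probes, n_per_group=config.meth_n_per_group,
            frac_dmp=config.meth_frac_dmp, delta_m=config.meth_delta_m,
            seed=seed)
        write_tsv(beta, outdir / "beta.tsv", cfg_hash, index=True,
                  index_label="probe")
        write_tsv(state_map.to_frame(), outdir / "probe_states.tsv", cfg_hash,
                  index=True, index_label="probe")
        write_tsv(truth, outdir / "truth_methylation.tsv", cfg_hash)
        filtered = methylation.filter_probes(beta)
        groups = {s: ("treated" if s.startswith("trt") else "control")
                  for s in beta.columns}
        m = methylation.beta_to_m(filtered)
        dmps = methylation.differential_methylation(
            m, groups, control="control", treated="treated",
            lfc_cutoff=config.dmp_lfc_cutoff, fdr_cutoff=config.dmp_fdr_cutoff)
        write_tsv(dmps, paths[0], cfg_hash, index=True, index_label="probe")
        means = methylation.mean_methylation(filtered)
        write_tsv(means.to_frame("mean_beta"), outdir / "mean_methylation.tsv",
                  cfg_hash, index=True, index_label="sample")
        enr = methylation.chromatin_state_enrichment(
            dmps, filtered.index, state_map)
        write_tsv(enr, paths[1], cfg_hash)
        return enr

    stage("methylation", ["dmps.tsv", "state_enrichment.tsv", "beta.tsv",
                          "probe_states.tsv", "truth_methylation.tsv",
                          "mean_methylation.tsv"],
          compute_methylation,
          lambda paths: pd.read_csv(paths[1], sep="\t", comment="#"))

    manifest = {
        "tool": "chemreprog",
        "version": __version__,
        "config_hash": cfg_hash,
        "config": dataclasses.asdict(config),
        "seed": seed,
        "deviations": DEVIATIONS,
        "stages": stages,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
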