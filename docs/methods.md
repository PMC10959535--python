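# Methods

This note documents the statistical procedures implemented in
`chemreprog`, the choices made where a design was genuinely open, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Splicing quantification and testing

Percent spliced-in for one event in one sample is

    Ψ = (I / l_I) / (I / l_I + S / l_S)

with `I`, `S` the inclusion- and skipping-supporting junction read counts
and `l_I`, `l_S` the effective lengths of the two isoform forms. Ψ is
reported as missing when `I + S` falls below a minimum coverage
(default 10 reads, an rMATS-like working convention) or when both counts
are zero.

Differential splicing compares two replicate groups with Welch's t-test
on per-replicate Ψ, a deliberate substitution for the hierarchical
likelihood model of junction-count tools: it is deterministic,
replicate-aware, and adequate at n = 4 per group. Events with fewer than
two non-missing replicates in either group are reported untested and
excluded from the BH family. Selection requires `|ΔΨ| > 0.1` together
with BH FDR < 0.05 by default; a raw p < 0.05 mode is exposed because
both variants appear in practice. ΔΨ is treated minus control.

### Consequence classification

Each event is anchored to one annotated transcript; the form that differs
from that transcript (exclusion for a skipped exon, inclusion for a
retained intron, and so on) is the alternative whose consequence is
predicted. The alternative form is re-spliced, its CDS offset re-derived
from the unchanged start codon, and its ORF re-translated. Categories are
assigned with the precedence

    noncoding_region > frameshift > premature_stop > domain_loss > no_disruption

- *noncoding_region*: the altered segment has no overlap with the genomic
  CDS window;
- *frameshift*: the net coding-length change is not a multiple of 3
  (checked before translation — frameshift subsumes most downstream
  stops, and the precedence makes the five categories mutually exclusive
  and deterministic);
- *premature_stop*: the re-translated ORF terminates strictly before the
  position the canonical stop would occupy after accounting for the
  in-frame length change. No NMD junction rule is applied by default; a
  last-junction variant is available via `nmd_rule=True`;
- *domain_loss*: the removed in-frame peptide interval overlaps an
  annotated domain, or an in-frame insertion point falls strictly inside
  one. Domains are supplied in protein coordinates per transcript;
- *no_disruption*: none of the above.

Events that would remove the start codon raise an error rather than
receive a category; the five-category scheme has no slot for them and the
generator never produces them.

The damage statistic is the fraction of events in
{frameshift, premature_stop, domain_loss}, computed either over the
selected differential events (differential mode) or per sample over all
covered events whose damaging isoform has Ψ ≥ 0.1 (standing mode; the
presence threshold is aligned with the ΔΨ cutoff since nothing else pins
it down). Group comparisons of per-sample damage go through the shared
one-way ANOVA with pairwise Welch post-hoc tests.

## Expression

Genes are kept when at least 20% of samples (boundary inclusive) have at
least 5 reads. Size factors are median-of-ratios: per sample the median,
over genes positive in all samples, of count / geometric mean (the median
taken on the ratio scale, which matters for even gene counts).
Differential expression is a per-gene Welch t-test on
`log2(normalized + 1)` — the +1 pseudo-count makes zeros representable —
with logFC defined as the difference of group means on that scale and BH
adjustment across tested genes. This replaces a negative-binomial GLM on
purpose: the downstream consumers (ranking metric, signatures, clocks)
need only (p, logFC), and a simple documented test keeps the pipeline
self-contained. Under the simulated global null its p-values are uniform
(KS distance < 0.05 at 5000 genes) and its empirical FDR is at or below
nominal in the recovery tests.

## Pre-ranked GSEA

Genes are ranked by `-log10(p) × sgn(logFC)` (p floored at 1e-300 to keep
the metric finite), descending, ties broken by gene identifier so runs
are reproducible across platforms. For a set S in a universe of N ranked
genes the enrichment score is the signed extremum of the running sum that
increments by `|metric|^w / Σ_S |metric|^w` at members (w = 1 by default)
and decrements by `1/(N − |S|)` otherwise. The null distribution draws
random same-size gene sets from the universe with a seeded generator
(gene-set permutation, matching the cited preranked tools, not phenotype
permutation); p is the add-one fraction of same-sign null scores at least
as extreme, NES is ES divided by the mean |null ES| of the same sign, and
BH runs across the sets of one call. Defaults: 5000 permutations, minimum
set size 5, FDR cutoff 0.1. Sets that shrink below the minimum inside the
universe produce per-set error records; the run continues.

Signatures are the top 500 genes by |logFC| among those with adjusted
p < 0.05 (optionally split into up/down sets); signature pairs are
compared by Spearman ρ of logFC over the union of each table's top 650
genes by p-value, restricted to the shared universe.

## Transcriptomic clocks

A clock is `tAge = intercept + Σ_g w_g · (x_g − μ_g)/σ_g` with
`x_g = log2(expr_g + 1)`. "Scaling" is interpreted as z-scaling against
the training statistics stored in the model file — the only reading under
which imputing undetected genes "with precalculated average values" is
coherent — and imputation happens on the log scale before scaling.
Per-sample standardization is available as an alternative mode. Group
contrasts of tAge are independent Welch t-tests per (treated, control)
pair within an age stratum. Predictions flag how many genes were imputed;
an all-imputed prediction equals the intercept when imputation values
coincide with training means.

## DNA methylation

Probes with any missing value or any detection p > 0.01 are removed.
M-values are `log2(β/(1−β))` with β clamped into [1e-6, 1−1e-6] so the
transform stays finite at the boundaries. Differential methylation is a
per-probe Welch test on M (ordinary tests, not moderated ones — at the
simulated group sizes moderation changes little and the statistics stay
self-contained), `lfcM` the difference of group means on the M scale (the
reading adopted for the ambiguous "log2FC of M-value" phrasing), and DMPs
require `|lfcM| > 1` with BH FDR < 0.05.

Chromatin-state enrichment builds, per (state, direction ∈ {hyper, hypo}),
the 2×2 table of state membership against DMP membership over the
analysis universe — defined as the probes surviving the filter, since
that is the set actually tested. The odds ratio uses Haldane's +0.5
correction when any cell is zero; the p-value is the exact hypergeometric
upper tail for enrichment (OR > 1) and lower tail for depletion, all
(state × direction) tests entering one BH family; results are reported as
`sign(OR − 1) × (−log10 adjusted p)`. Probes mapped to more than one
state keep the first-listed state.

## Synthetic data

The generator exists so that every stage has ground truth. What it
emulates, per stream (one global seed expands to independent per-stream
child seeds, so changing one stage's parameters never perturbs another):

- **Annotation** — one gene per toy chromosome, alternating strands, a
  fixed skeleton (5'UTR, three coding exons around a designed internal
  exon, stop codon, a split 3'UTR), and exactly one engineered splicing
  event per gene covering all five event types. Categories are realized
  by construction: exon lengths mod 3 force frameshifts, in-frame TAA
  codons embedded in retained introns or swapped exons force premature
  stops, domains placed over removed codons force domain loss, and
  UTR-placed events force the non-coding category. Coding sequence is
  built from non-stop codons so the reference ORF is clean, and
  codon-aligned junctions guarantee in-frame removals cannot create
  spurious stops. A requested category mix is realized exactly by
  largest-remainder allocation.
- **Junction counts** — `I ~ Binomial(depth, Ψ·l_I / (Ψ·l_I + (1−Ψ)·l_S))`,
  `S = depth − I`, per replicate; defaults 4 replicates per group at
  depth 200, control Ψ 0.5, treated shifts of ±0.3 (retained introns
  shifted negative, matching the direction structure such studies
  report).
- **Gene counts** — negative-binomial with log-uniform base means
  (20–500), dispersion 0.1, log-normal library factors (sd 0.3), and a
  10% DE fraction at |logFC| = 2 by default — sizes of the order of a
  small bulk RNA-seq contrast.
- **Methylation** — per-probe M baselines set by chromatin state
  (enhancer −1, promoter −3, heterochromatin +3, quiescent 0, jitter
  sd 0.5), Gaussian noise sd 0.3, and true DMPs (5%) shifted by ΔM = 2,
  80% of them placed in a designated target state so state enrichment has
  signal; β is the logistic transform, hence always in [0, 1].
- **Clock studies** — gene expression constructed by inverting the clock
  (z ∝ w), so noiseless data reproduce the target ages exactly; Gaussian
  noise sd 1 on the log2 scale; optional per-sample rejuvenation shifts
  (default −5 age units for treated samples in the pipeline's two-age ×
  two-condition design at n = 4).

What it does **not** emulate: read-level alignment artifacts, overdispersed
or correlated junction counts, isoform-expression coupling, batch
effects, array normalization quirks, probe cross-reactivity, or realistic
genome scale. Passing the recovery tests therefore demonstrates the
correctness of the statistics on their stated models, not robustness to
the failure modes of real sequencing data.

## Numerical choices and degenerate inputs

- Welch tests on two constant groups return t = 0, p = 1 when means agree
  and p = 0 with a `zero_variance` warning flag when they differ, so
  synthetic edge cases cannot crash a run while staying auditable.
- BH adjustment is the step-up procedure; it is monotone and capped at 1
  but *not* idempotent (the package's tests verify it against a literal
  O(m²) oracle instead).
- GSEA normalizer sums are taken over masked (in-set) weights only, which
  keeps the enrichment score bit-identical to the textbook running sum.
- Ranked-list ties break by gene identifier; permutation draws iterate
  sets in sorted name order, making results bit-reproducible per seed.
- Tukey-style post-hoc contrasts are implemented as pairwise Welch tests
  with BH correction rather than the studentized range; the substitution
  is recorded in every run manifest.
- Damage proportions over zero qualifying events raise an explicit
  undefined-result error rather than returning NaN.

## Pipeline sizes and runtime

The default `run-all` configuration (40 genes/events, 1000 genes × 8
samples, 1000 probes × 10 samples, 50 clock genes × 16 samples, 5000
GSEA permutations) was chosen as the smallest study at which every stage
has clear signal; it completes in well under a minute on one CPU and its
outputs are byte-reproducible per seed. The null-calibration tests use 20
simulation repeats at 300 events / 1000 genes / 1000 probes per repeat.

## Limitations

- One transcript anchors each event; multi-isoform weighting and
  ribosome-informed ORF calling are out of scope.
- Only two-group comparisons (per stratum) are supported; no paired
  designs, interactions, or mixed models.
- Premature-stop calling does not model NMD efficiency; the optional
  junction rule is a coarse proxy.
- Clock training is out of scope: the package applies linear clocks, it
  does not fit them, and published clock coefficients must be supplied as
  model files.
- The stop-loss case (an event removing the canonical stop without a new
  in-frame stop) has no category of its own and is reported as
  no_disruption.
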