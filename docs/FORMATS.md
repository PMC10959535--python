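# File formats

All tabular files are tab-separated with a header row; lines starting
with `#` are metadata (pipeline outputs carry
`#chemreprog <version> config=<hash>` as their first line) and are
skipped by every reader. Coordinates in files are 1-based inclusive for
GTF and 0-based half-open for BED-dialect and event files, matching the
conventions of those formats.

## Inputs

### Genome FASTA
Standard multi-record FASTA; sequences are uppercased on load and must
contain only A/C/G/T/N.

### Annotation GTF
Standard 9-column GTF. Only `exon` and `CDS` features are used; each
transcript needs both, with `gene_id` and `transcript_id` attributes.
The CDS span must lie inside the exon union.

### Domain BED (protein coordinates)
BED dialect where the first column carries the *transcript id* and the
interval is in amino acids (half-open numeric convention, so
`t1  9  43  MyDomain` means residues 10–43 inclusive).

### Event definitions (`events.tsv`)
`event_id  type  gene_id  transcript_id  alt_region  len_inclusion  len_skipping`
with `type` in {SE, RI, A5SS, A3SS, MXE} and `alt_region` encoded as
`start-end` (two comma-separated intervals for MXE; the first is the exon
carried by the inclusion form).

### Junction counts
Long table: `event_id  type  sample  group  inclusion_count
skipping_count  len_inclusion  len_skipping` (`type`/`group` optional for
the Psi computation itself).

### Groups file
`sample  group` — used by the CLI subcommands that need a sample → group
map.

### GMT gene sets
Standard GMT: set name, description, then tab-separated member genes.

### Clock model
First line `#intercept=<float>`, then
`gene  weight  training_mean  training_sd  imputation_value`.

### Beta matrix / probe states
`probe` × sample matrix of β values in [0, 1]; the state map is
`probe  state`.

## Outputs

- `psi_matrix.tsv` — `event_id  sample  psi  coverage` (psi empty below
  min coverage).
- `diff_splice.tsv` — `event_id  mean_psi_control  mean_psi_treated
  delta_psi  p_value  tested  fdr  selected`.
- `direction_summary.tsv` — `type  n_positive  n_negative` over selected
  events.
- `consequence_calls.tsv` — `event_id  transcript_id  category
  altered_aa_start  altered_aa_end  new_stop_aa`.
- `damage_differential.tsv` / `damage_standing.tsv` — damage proportions
  per comparison / per sample.
- `de.tsv` — `gene  lfc  pv  fdr`.
- `signature_association.tsv` — `condition  set  size  es  nes  p_value
  error  fdr  significant  stars`.
- `tage_predictions.tsv` — `sample  tAge  n_imputed  fully_imputed`;
  `tage_comparisons.tsv` — `group_a  group_b  effect  statistic  df
  p_value  fdr`.
- `dmps.tsv` — `probe  lfcM  pv  fdr  direction  selected`.
- `state_enrichment.tsv` — `state  direction  n_state  n_dmp  overlap
  odds_ratio  p_value  adj_p  signed_log10_adj_p`.
- `manifest.json` — tool version, config hash and full config, seed,
  documented method substitutions, and per-stage output checksums.
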