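# methyloscope

A whole-genome bisulfite sequencing (WGBS) methylome analysis toolkit for
blood-type population epigenetics, exercised end-to-end on synthetic genomes
and methylomes with planted ground truth.

The pipeline covers:

- **Quality control** — strand collapse of CpG counts, per-sample depth
  filters (retain 10 ≤ depth ≤ 500 in every sample), presence-in-all-samples
  filter, SNP masking (a variant on either base of the CpG dinucleotide
  removes the site), sex-chromosome exclusion, β = meth/total computation,
  pairwise Spearman correlation, bisulfite conversion rate, and scaled gene
  meta-profiles.
- **CpG-island tools** — de novo detection under two printed criteria sets
  (GC > 0.5, O/E > 0.6, length > 200 bp; and GC ≥ 0.55, O/E ≥ 0.65,
  length ≥ 500 bp), methylation classing (unmethylated < 0.1 ≤ low ≤ 0.5 <
  high), promoter/shore/shelf/"others" feature catalogs, and gene-end island
  presence.
- **Region calling** — per-CpG one-way ANOVA (breed), two-group ANOVA (sex),
  logistic regression with covariates (condition), Spearman age correlation,
  Benjamini–Hochberg FDR, and greedy chaining of significant or high-SD CpGs
  into regions (gap ≤ 100 bp, ≥ 5 members).
- **Enrichment** — binomial over/under-representation of high-variability
  CpGs across genomic features, one-tailed repeat-subfamily enrichment per
  island methylation class (subfamilies overlapping < 100 islands omitted),
  and generic hypergeometric gene-set tests.
- **Sequence embedding** — a native byte-pair-encoding tokenizer, a pure-numpy
  bidirectional transformer encoder trained with a masked-token objective
  (no next-sentence task, [PAD]/[MASK] only), mean-pooled per-island vectors,
  t-SNE projection, and silhouette/linear-probe class-separation scores.
- **Synthetic data** — CpG-depleted background genomes with planted CpG-rich
  islands, beta-binomial methylation counts with planted breed effects,
  high-variance loci and age-correlated loci, plus gene/repeat/CTCF/SNP
  annotations — all deterministic from a single seed.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion (oracle
equivalence for the island detector and run merging, planted-effect recovery,
type-I calibration, exact-test oracles, filter semantics, tokenizer
invariants, embedding class separation). The embedding criterion trains a
desk-scale model (2 layers, 64 dims, vocab 512, 20 epochs) and takes a few
minutes on one CPU.

## CLI

Each stage reads/writes a single run directory and records a manifest
(config hash, seed, package version, input checksums):

```bash
methyloscope simulate --config config.yaml --out run/
methyloscope qc       --config config.yaml --out run/
methyloscope cgi      --config config.yaml --out run/
methyloscope dmr      --config config.yaml --out run/
methyloscope varreg   --config config.yaml --out run/
methyloscope enrich   --config config.yaml --out run/
methyloscope embed    --config config.yaml --out run/
# or everything at once:
methyloscope all      --config config.yaml --out run/
```

Exit codes: 0 success, 2 configuration problem / missing input, 3 data error.
A minimal config:

```yaml
seed: 1
simulate:
  seed: 1
  chrom_length: 200000
  n_cgis: 6
  n_auto_dmrs: 2
  background_cpg_rate: 0.01
  n_samples_per_breed: {shiba: 3, poodle: 3, dachshund: 3}
dmr: {fdr: 0.05, gap_bp: 100, min_count: 5}
varreg: {fraction: 0.01, gap_bp: 100, min_count: 5, alpha: 0.01}
embed: {vocab_size: 512, epochs: 5}
```

Key outputs: `filtered_matrix.tsv` (chrom, 1-based pos, per-sample β),
`correlation.tsv`, `cgis.bed` (name = methylation class, score =
round(1000·mean β)), `dmrs.bed`, `variable_regions.bed` +
`variable_region_assoc.tsv`, `feature_enrichment.tsv`,
`repeat_enrichment.tsv`, `embeddings.tsv`, `tsne.tsv`, `separation.json`,
and `ground_truth.json` with every planted feature.

## Coordinates

Internal coordinates are 0-based half-open everywhere. The only 1-based
surfaces are the methylation count table (`pos` column) and human-readable
reports. Methylation tables are 5-column TSVs
(chrom, 1-based pos, strand, meth, total) in either a per-strand or a
pre-collapsed flavor; a site absent from a sample's table means "no data",
never zero counts.
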