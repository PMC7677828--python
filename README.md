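# haplokit

A case-control haplotype association toolkit for a single deeply sequenced
locus. It covers the full analysis chain from genotypes to downstream
molecular readouts:

- **`haplokit.synth`** — synthetic cohort generator: three nested ancestral
  haplotypes, stratum-specific frequencies, retrospective case-control
  sampling with exact per-haplotype odds ratios, an additive cis-regulatory
  effect on a target gene, planted differentially expressed genes, and
  antigen-specific serology shifts.
- **`haplokit.qc`** — sample filters (call rate, fold coverage), per-variant
  MAF/call-rate/HWE statistics (exact and chi-square tests), frequency
  classes and region density summaries.
- **`haplokit.assoc`** — allelic 2×2 tests with Woolf CIs, median-based
  genomic-control correction, Benjamini–Hochberg FDR,
  Cochran–Mantel–Haenszel stratified tests, and conditional scans on a peak
  variant.
- **`haplokit.haplo`** — EM haplotype-frequency estimation over
  phase-compatible pairs, pairwise LD (D, D′, r²), D′-based tag-set
  selection, per-haplotype stratified association, maximum-posterior
  diplotype assignment and dose-effect tests.
- **`haplokit.mjnet`** — median-joining networks over haplotype bit-vectors
  with case/control node composition; GraphML and DOT export.
- **`haplokit.eqtl`** — rank-based inverse-normal normalization with
  covariate residualization, cis-eQTL dosage regression, diplotype-ordered
  expression trends.
- **`haplokit.de`** — internal-standards differential expression: reference
  group selection by an iterative F screen, two-step normalization,
  replicate Student t plus an associative T test against the pooled
  reference residuals, fold and expression-floor filters.
- **`haplokit.serology`** — control-channel NFI normalization, genotype-group
  fold enrichment, antigen clustering order.
- **`haplokit.vcfio` / `haplokit.pipeline` / `haplokit.cli`** — VCF 4.2 and
  TSV I/O, configuration, and the end-to-end pipeline.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (printed
arithmetic, parameter recovery, oracle equivalence against brute-force
references, and statistical calibration).

## CLI

```sh
haplokit pipeline --seed 1 --out-dir results/run1      # simulate + all stages
haplokit simulate --config config.json
haplokit qc --vcf genotypes.vcf --samples samples.tsv --out-dir out
haplokit de --config config.json
```

Stage outputs (variant stats, association TSVs, haplotype tables, GraphML
network, eQTL and DE results, serology enrichment) land in the output
directory together with a `manifest.json` and a machine-readable exclusion
log. Same config + seed reproduces byte-identical outputs.

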