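# txpopgen

Population divergence and diversity analysis for transcriptome-derived
biallelic SNPs: a GATK-style hard-filter cascade, per-SNP two-population
differentiation statistics (G_ST, Hedrick's G'_ST, Jost's D, AMOVA
phi_ST) with Fisher exact-test significance under Bonferroni correction,
per-unigene nucleotide diversity and Tajima's D with percentile outlier
calling, synonymous/nonsynonymous/UTR/noncoding SNP classification
against transcript ORFs, and complete-case genotype PCA with a k-means
cluster summary. A Balding–Nichols synthetic-data generator (including a
hidden-subpopulation "standing variation" scenario) makes every stage
testable without external data.

## Inputs

* **VCF 4.x** with per-sample `GT` (and optionally `GQ`) and site-level
  INFO `FS`, `QD`, `DP`. `CHROM` is the unigene id, `POS` the 1-based
  transcript coordinate. Only biallelic SNPs are used; indel and
  multiallelic lines are skipped and counted.
* **Transcript FASTA** of unigene consensus sequences.
* **ORF annotation TSV** with columns `unigene_id`, `length`,
  `orf_start`, `orf_end` (empty = no ORF; ORF length must be divisible
  by 3).
* **Sample sheet TSV** with columns `sample_id`, `population`
  (exactly two populations for the divergence statistics).

## Command line

```bash
# generate a synthetic fixture (VCF + FASTA + TSVs + ground-truth manifest)
txpopgen simulate --n-genes 500 --n-per-pop 48 --seed 1 --out fixture/

# full pipeline
txpopgen run-all \
    --vcf fixture/snps.vcf --fasta fixture/transcripts.fasta \
    --annot fixture/annotations.tsv --samples fixture/samples.tsv \
    --out results/

# individual stages
txpopgen filter --vcf in.vcf --samples pops.tsv --out kept.vcf --gq-min 20
txpopgen divergence --vcf kept.vcf --samples pops.tsv --out divergence.tsv
txpopgen diversity --vcf kept.vcf --samples pops.tsv --annot orfs.tsv --out pi.tsv
txpopgen effects --vcf kept.vcf --samples pops.tsv --fasta tx.fa --annot orfs.tsv --out classes.tsv
txpopgen structure --vcf kept.vcf --samples pops.tsv --out structure/
```

`run-all` writes `filter_summary.tsv`, `divergence.tsv`,
`divergence_summary.tsv`, `diversity.tsv`, `effect_summary.tsv`,
`pca_scores.tsv`, `pca_variance.tsv`, `clusters.tsv` and a
`manifest.json` with per-stage counts. Identical inputs and config give
byte-identical reports. Flags override config-file values, which
override defaults.

## Filter cascade

Genotypes with `GQ < 20` are masked to "no call" first; sites are then
removed, in deterministic attribution order, by: FisherStrand > 30,
quality-by-depth < 2, more than 3 SNPs in any 35-bp window, site depth
< 25, fewer than 16 called individuals in either population, and pooled
minor allele frequency < 1%. All thresholds are CLI/config options.

## Statistics notes

* Hs/Ht use Nei–Chesser bias-corrected estimators by default
  (harmonic-mean sample size, observed heterozygosity correction); the
  textbook uncorrected estimators are available via `--uncorrected`.
* Tajima's D uses the gene's *average* called allele count as the
  sample size; harmonic-number constants are generalized to real n via
  the digamma identity (an integer mode exists for cross-checks).
* Per-gene diversity is reported both per transcript length and per SNP
  site, for each population separately.

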