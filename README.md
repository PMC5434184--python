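# l1peak

Detection and analysis of mobile-element insertion sites from 3'-anchored
hemi-specific amplicon sequencing, built around a synthetic-data generator so
the whole pipeline is testable end to end without any external data.

The package covers:

- **`l1peak.synth`** — toy genomes, gene models, KR/KNR element catalogs,
  planted insertions with zygosity and mosaic fraction per individual,
  pooled 100-nt amplicon reads (10-nt primer + 64-nt genomic flank + 26-nt
  tail, with PCR duplicates, base errors and off-target noise), and droplet
  counts under a Poisson partition model.
- **`l1peak.reads`** — the fixed trim rule (10 nt off the 5' end, 26 nt off
  the 3' end), strict per-base Q ≥ 30 filtering, a small exact-seed toy
  aligner, and SAM/FASTQ I/O (external SAM/BAM can be ingested instead of
  using the toy aligner).
- **`l1peak.calling`** — strand-aware single-linkage peak calling in a 64-nt
  window, per-pool read/unique-start counts, k-mer mappability, the
  "original" (`mean_mapq ≥ 30`, `mapscore > 0.5`, `maxcount > 5`,
  `maxuniq > 1`) and "new" (`mean_mapq ≥ 30`, `mappability > 0.5`,
  `mean_matchpct > 0.98`, `total_reads > 5`, `unique_alignments > 1`)
  filter profiles, KR/KNR/novel classification against catalogs, and
  intragenic/intergenic annotation (exon, intron, or within 500 bp of a
  TSS or 3'UTR end).
- **`l1peak.popcompare`** — cross-pool call merging, cocaine-only /
  control-only / shared exclusivity, an exact two-sided Fisher test, and
  per-individual call rates.
- **`l1peak.enrich`** — hypergeometric (DAVID-style) and binomial
  (PANTHER-style) gene-set over-representation with fold enrichment and
  Bonferroni correction; GMT input.
- **`l1peak.ddpcr`** — droplet digital PCR concentration estimation
  (λ = −ln(1 − positive fraction), Wilson-interval CIs), allele-ratio
  zygosity interpretation, reference-normalised expression (including the
  geometric-mean normaliser), and an exact/two-sided Wilcoxon rank-sum test.
- **`l1peak.pipeline` / `l1peak.cli`** — one-seed orchestration of
  simulate → trim/filter/align → call → compare → enrich with a JSON run
  report (recall/precision against planted truth, exclusivity counts,
  Fisher p, enrichment tables).

## CLI

```bash
l1peak run-all --seed 1 --outdir out/           # full synthetic pipeline
l1peak simulate --seed 1 --outdir out/          # inputs only
l1peak align --genome out/genome.fa --fastq out/coc_pool1.fastq --out p1.sam
l1peak call --genome out/genome.fa --sam p1.sam \
    --catalog out/catalog.bed --genes out/genes.tsv --profile new --out p1.peaks.tsv
l1peak compare --peaks coc_pool1 p1.peaks.tsv --peaks con_pool1 q1.peaks.tsv \
    --manifest out/pools.tsv --out exclusivity.tsv
l1peak enrich --genes query.txt --gmt terms.gmt --test binomial --out enrich.tsv
l1peak ddpcr quantify --counts droplets.csv --out quant.csv
l1peak ddpcr ratio --counts droplets.csv --out ratios.csv
l1peak ddpcr expression --table expression.csv --out expr_ratios.csv
```

All stages accept a YAML config (`--config`); every piece of randomness is
derived from the single master seed, so reruns are byte-identical.

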