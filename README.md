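# splicedyn

Differential exon usage, effect sharing, trajectory clustering and
GWAS-interval enrichment for differentiation time-course RNA-seq — with a
matched synthetic-data generator so the whole pipeline is testable
end-to-end without any restricted data.

## The problem

Adipocyte differentiation (preadipocytes sampled at confluence, day 3 and
day 15 of differentiation) remodels not only gene expression but also
alternative splicing, and the two respond largely independently: a gene
can swap exons in and out of its transcripts with no change in overall
output. `splicedyn` implements the analysis stack for asking, across
several metabolic cohorts (lean, obese, obese with T2D):

1. **Which exons change usage between time points?** Differential exon
   usage (DEU) per cohort and consecutive time-point pair, with technical
   sequencing runs as a fixed-effect covariate.
2. **Which genes change expression?** Gene-level negative-binomial Wald
   tests with the dual rule FDR < 0.05 *and* fold change ≥ 1.25.
3. **How much do cohorts share?** Pairwise sharing of significant
   effects: same sign and magnitudes within a factor of 0.5.
4. **What are the splicing dynamics?** Fuzzy c-means clustering (k = 6)
   of centered/scaled usage-coefficient trajectories, max-membership
   assignment, per-cluster prevalence.
5. **Do disease SNPs concentrate near these exons?** Count of flanking
   introns overlapping ≥ 1 SNP versus 1000 size-matched control exon
   sets; empirical percentile > 0.95 ⇒ enriched, < 0.05 ⇒ depleted.

## The model

For exon *i* of gene *g* in sample *s*, the DEU test models the count
pair (this exon, sum of the gene's other exons) as negative binomial with
log link:

    log μ = β₀ + β_bin·bin + β_cond·cond + β_run·run + β_int·(bin × cond) + log sf_s

where `bin` indicates the exon versus the rest-of-gene bin, `cond` the
second time point, and `sf_s` a median-of-ratios size factor.  `β_int` is
the log usage fold change — a change in the exon's share of its gene's
reads, independent of the gene's expression level — and its
likelihood-ratio test gives the DEU p-value.  Dispersions are
method-of-moments estimates shrunk 50/50 toward a mean-count trend,
estimated separately for the exon and rest bins (the rest bin is an
aggregate and is systematically less dispersed).  Benjamini–Hochberg
correction is applied per comparison; q < 0.05 calls an exon
differentially used.

The synthetic-data generator draws the full study design (3 cohorts ×
3 time points × 3 subjects × 2 technical runs) from the same family:
gene-level expression structure, within-gene exon shares via softmax
weights, NB sampling, run-specific library factors — and records every
planted (and compositionally induced) usage or expression shift as
ground truth.

## Worked example

```sh
splicedyn run --config configs/demo.yaml
```

simulates 50 genes (247 exons, 54 samples), plants usage shifts in 10% of
eligible exons and expression shifts in 10% of genes, spikes SNPs into
the flanking introns of the early-differentiation usage shifts, and runs
every stage.  From `splicedyn_demo/summary.json`:

- `exon_usage` — 25–43 exons at FDR < 0.05 per cohort/comparison
  (e.g. `lean:confluence-vs-day3: 41`).
- `sharing` — mean pairwise sharing 0.24 between splicing analyses,
  0.25 between expression analyses, but only 0.16 between splicing and
  expression: the two regulatory layers overlap weakly even with
  co-planted effects.
- `clustering` — six usage-trajectory clusters per cohort with
  prevalences summing to 100% (lean: 16.7/21.8/25.6/11.5/12.8/11.5%).
- `gwas_enrichment` — the spiked early-differentiation comparisons rank
  high (percentiles 0.85, 0.60, 0.97 — the last called `enriched`)
  while late comparisons rank low (0.09, 0.006 `depleted`, 0.037),
  matching where the SNPs were planted.

Each stage is also a subcommand (`splicedyn simulate | deu | share |
cluster | gwas-enrich`) over the TSV/GFF3/BED interchange files, and a
library API (`splicedyn.exon_usage`, `.sharing`, `.clustering`,
`.gwas`, `.simulate`).

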