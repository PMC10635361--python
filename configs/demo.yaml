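# Demo pipeline: 50 genes, full three-cohort design, planted usage and
# expression shifts, SNPs spiked into the flanking introns of exons with
# early-differentiation usage shifts.
outdir: splicedyn_demo
n_genes: 50
sim:
  ds_fraction: 0.1
  de_fraction: 0.1
n_background_snps: 150
n_spiked_snps: 400
seeds:
  simulate: 1
  snps: 2
  clustering: 3
  enrichment: 4
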