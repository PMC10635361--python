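# Methods

## Scope and data model

`splicedyn` analyses exon-level count tables from a differentiation time
course: rows are exons grouped by gene (a "flattened" annotation with
one `exonic_part` per exon), columns are samples annotated with cohort,
time point, subject and technical sequencing run.  All genomic
coordinates are 0-based half-open internally; GFF3 is converted to
1-based inclusive on write and back on read, BED is written as-is.
Alignment and read counting are upstream of the package: it consumes
counts, not reads.

## Synthetic data generator

The generator emulates the study conditions the statistics are designed
for: cohorts `lean, obese, obese_T2D`; ordered time points `confluence,
day3, day15`; 3 subjects per cohort; 2 technical runs per sample.

Counts are drawn hierarchically:

- Gene baseline expression θ_g ~ lognormal(0, 1), normalized to sum to
  one and scaled by the expected per-sample depth (default 5e6 exonic
  counts; sequencing depth is a free parameter of the generator since it
  is a property of the experiment, not the method).
- Exon shares within a gene come from positive weights
  w_e ~ lognormal(0, 0.5) normalized per gene (softmax).  A planted
  usage effect multiplies one exon's weight by 2^δ; gene expression and
  exon usage are therefore independently controllable.
- A planted effect for the comparison (tA, tB) switches on at tB and
  persists through later time points, so each effect is visible in
  exactly one consecutive-pair contrast.
- Samples are NB draws (gamma–Poisson) with dispersion α = 0.05 around
  mean depth × θ_g × share × run factor × lognormal(0, 0.05) jitter.
  Technical runs are independent draws around the shared
  subject × time-point mean times the run's library factor (defaults
  1.0 and 0.8), matching a fixed-effect run covariate downstream.
- Default planted-effect sizes where a scenario plants them:
  |log2 usage effect| 1.5, |log2 expression fold change| 1.0, fractions
  0.1, signs random, half the effects shared across all cohorts.

**Compositional truth.** Exon shares sum to one within a gene, so
boosting one exon necessarily depresses its siblings' usage.  The
generator records, besides the planted labels, the *exact* generative
log2 usage-odds change of every exon (`SimTruth.true_usage_shift`).
Recovery is scored with sensitivity on planted exons and precision
against truly-shifted exons; a sibling called significant is a genuine
discovery of a real induced shift, not a false positive.

What the generator does **not** emulate: sequence content, read-level
noise, isoform structure, correlated subjects (subjects are i.i.d.; the
NB dispersion absorbs biological variability), GC/mappability biases,
and linkage structure among SNPs.  Passing tests therefore demonstrate
correctness of the statistical machinery under a faithful NB
compositional model, not robustness to alignment artifacts or LD.

## Differential exon usage

Estimand: the change in an exon's share of its gene's reads between two
time points, within one cohort.  Each testable exon is fit as a two-bin
NB GLM on (exon count, rest-of-gene count) with terms
intercept + bin + condition + run + bin:condition and a log size-factor
offset (median-of-ratios over exons).  The bin:condition interaction is
the log usage fold change; its likelihood-ratio test against the
no-interaction model gives the p-value, a Wald z the signed score, and
per-time-point usage coefficients come from one joint fit over all time
points (bin + bin:timepoint terms).  This deliberately compresses the
exon-level testing idea of DEXSeq-style models into a this-exon-vs-rest
formulation; the per-gene joint model and empirical-Bayes dispersion
machinery of such tools are out of scope.

Numerical choices:

- **Batched IRLS.** All exons in a comparison share one design matrix,
  so the GLM is fit for all exons simultaneously (batched weighted
  least squares with step-halving, linear predictor clamped at ±30,
  convergence at |Δloglik| < 1e-8).  Unit tests pin the fits to
  statsmodels' per-unit NB GLM at 1e-5.
- **Dispersion.** Per-exon method of moments on size-factor-normalized
  counts within time-point × run groups, shrunk 50/50 toward the median
  of mean-count bins, floored at 1e-4 — estimated separately for the
  exon bin and the rest bin.  The rest bin aggregates several exons, so
  its dispersion is systematically lower
  (α_rest ≈ α·Σμ_i²/(Σμ_i)²); a single pooled value is dominated by
  the rest bin and miscalibrates the test (null p < 0.05 rate 0.14
  instead of ~0.06 in the calibration simulations).
- **Testability.** Exons with summed counts below `min_total` (default
  10) and genes left with fewer than two such exons are flagged
  untestable; untested exons carry NaN statistics and never enter the
  BH correction.
- BH is applied across the testable exons of one comparison; q < 0.05
  flags differential usage.  Swapping the comparison direction negates
  fold changes and leaves p-values unchanged by construction.

## Differential expression

Per-gene sums of exon counts, NB GLM with condition + run and the same
size factors, Wald test on the condition coefficient, BH correction.  A
gene is differentially expressed when q < 0.05 **and** |fold change| ≥
1.25 — the dual rule keeps trivially small but well-measured shifts out
of the significant set.

## Pairwise sharing

For two analyses (cohort × comparison × modality), the denominator is
the set of features significant (q < 0.05) in at least one analysis
with finite effects in both; the numerator is those whose effects have
the same sign and magnitudes within a factor of 0.5 of each other,
boundary inclusive; an exact zero shares sign with nothing.  Splicing
results are collapsed to genes (for cross-modality comparison) by the
minimum-p exon, ties broken by the lexicographically smallest exon id.

Sharing is computed on the *estimated* effects.  The empirical-Bayes
multivariate shrinkage some published analyses apply before this
criterion (mashr-style posteriors with lfsr significance) is
deliberately not reproduced; with shrinkage, near-boundary pairs would
migrate toward sharing, so estimate-based fractions are generally more
conservative.  This is the package's most consequential simplification
and is the reason its sharing numbers are not directly comparable to
posterior-based ones.

## Trajectory clustering

Input: the union of q < 0.05 exons over a cohort's two comparisons;
their three usage coefficients are centered and scaled per exon (sample
sd, n−1; constant trajectories are dropped with a warning).  Fuzzy
c-means with k = 6 and fuzzifier m = 2 (the conventional default; the
method is insensitive near 2 on well-separated shapes) minimizes
Σᵢⱼ uᵢⱼ^m ‖xᵢ−cⱼ‖² by alternating the standard membership and centroid
updates until the objective changes by < 1e-9 (max 1000 iterations).
Initialization is k-means++-style seeding; 5 restarts keep the best
objective; a point coinciding with a centroid gets membership 1 there.
Hard assignment is max membership, ties to the lowest cluster index;
prevalence is the percent of clustered exons per cluster.  Cluster
labels are arbitrary per cohort; cross-cohort correspondence uses
greedy minimum-Euclidean-distance centroid matching with an explicit
distance ceiling (default 1.0 on the standardized scale) beyond which a
centroid is reported cohort-specific.

The recovery check draws 600 trajectories from six canonical shapes
(up-up, down-down, up-down, down-up, up-flat, down-flat, amplitude ~2
on the coefficient scale) plus Gaussian noise σ = 0.3 — the amplitude
matches strong usage shifts so shape, not noise, dominates — and
requires ≥ 90% assignment accuracy; measured ~95%.

## GWAS-interval enrichment

The flanking introns of an exon are the gaps to its neighboring exons
within the gene model (strandless; terminal exons have one flank,
single-exon genes none).  The statistic is the number of *distinct*
flank intervals (deduplicated by identical coordinates only — adjacent
exons naming the same intron count it once) containing at least one SNP
under half-open semantics (a ≤ p < b).  The null is 1000 control sets
of the same size sampled uniformly without replacement from all tested
exons, independently per set; no length or expression matching is
applied.  The empirical percentile is the fraction of null counts
strictly below the observed; > 0.95 calls enrichment.  Ties count
against significance in both directions (depletion requires > 95% of
null counts strictly above the observed), so a degenerate null — every
control set equal to the observed — is "not significant" rather than
depleted.

Intersection is a per-chromosome sorted-positions binary search; a
precomputed exon → flank-id index turns the 1000 permutations into
unions of integer sets.  Both are pinned to a naive all-pairs scan in
tests.

Calibration note: with uniform SNPs and random exon sets, the
enriched-call rate sits slightly below 5% (the strict-inequality tie
rule is conservative on a discrete statistic); the calibration
simulations use a SNP density high enough (8000 SNPs over a 300-gene
genome) that the null distribution is well spread and the rate lands
within the binomial confidence band around 5%.  A real caveat the
simulations expose: exon sets that cluster within genes (as DEU calls
do — planted exons drag their siblings) share flanking introns and so
have systematically *fewer distinct* flanks than size-matched random
sets, biasing toward depletion calls.  Interpreting depletion for
within-gene-clustered sets therefore requires care; the power and
calibration checks use non-clustered sets.

## Pipeline

`splicedyn run --config config.yaml` executes simulate → DEU/DGE →
sharing → clustering → enrichment with per-stage seeds, writes every
stage's tables plus `summary.json` and a `manifest.json` (sha256 of all
text outputs, seeds, package version; no timestamps), and is
byte-identical on rerun with the same config.  Stage failures abort
with the stage named in the error.  The demo configuration uses 50
genes, 150 background SNPs and 400 SNPs spiked into flanks of
early-differentiation planted exons — sized so the whole run takes a
few seconds while every stage has signal to find.

## Problem sizes used in checks

Calibration and recovery simulations use 200 four-exon genes under the
full study design (10 replicates); enrichment calibration uses 200
datasets of 300 genes with 1000 permutations each; clustering recovery
uses 600 trajectories.  These sizes give Monte-Carlo error comfortably
inside the asserted bands while the full suite runs in well under a
minute.

## Known limitations

- The DEU model tests each exon against the rest of its gene
  independently; correlated exons within a gene are not jointly
  modelled, and p-values for sibling exons of a true effect are
  genuinely (and correctly) small due to compositionality.
- Dispersion estimation at n = 3 subjects leans on the trend shrinkage;
  strongly exon-specific dispersion will be over-smoothed.
- Sharing on estimated effects (no shrinkage), as discussed above.
- Enrichment controls are size-matched only; length- or
  expression-matched controls are not implemented.
- Single-assembly coordinates are assumed throughout; no liftover.
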