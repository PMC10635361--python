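"""Synthetic data for the differentiation time-course splicing pipeline.

Emulates the study layout the downstream statistics expect: three
metabolic cohorts (lean, obese, obese with T2D) sampled at confluence,
day 3 and day 15 of adipocyte differentiation, three subjects per cohort,
each sample sequenced in two technical runs.  Counts are negative
binomial with gene-level expression structure; exon usage is controlled
separately from gene expression through within-gene exon weights
(softmax), so usage shifts and expression shifts can be planted
independently.  Every planted effect is recorded in a :class:`SimTruth`
so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import ExonCountTable
from .intervals import GeneModel, GenomicInterval

Comparison = tuple[str, str]
AnalysisKey = tuple[str, Comparison]


@dataclass(frozen=True)
class StudyDesign:
    """Cohorts x ordered time points x subjects x technical runs."""

    cohorts: tuple[str, ...] = ("lean", "obese", "obese_T2D")
    timepoints: tuple[str, ...] = ("confluence", "day3", "day15")
    subjects_per_cohort: int = 3
    runs_per_sample: int = 2

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("need at least two time points")
        if self.subjects_per_cohort < 1 or self.runs_per_sample < 1:
            raise ValueError("subjects and runs must be >= 1")

    @property
    def comparisons(self) -> list[Comparison]:
        """Consecutive time-point pairs, the tested contrasts."""
        return list(zip(self.timepoints, self.timepoints[1:]))

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for c in self.cohorts:
            for t in self.timepoints:
                for s in range(1, self.subjects_per_cohort + 1):
                    for r in range(1, self.runs_per_sample + 1):
                        rows.append(
                            {
                                "sample": f"{c}_{t}_s{s}_r{r}",
                                "cohort": c,
                                "timepoint": t,
                                "subject": f"{c}_s{s}",
                                "run": f"run{r}",
                            }
                        )
        return pd.DataFrame(rows)


@dataclass
class SimParams:
    """Generative parameters for :func:`simulate_counts`.

    depth
        Expected exonic counts per sample (library size before run and
        jitter factors).
    dispersion
        NB2 dispersion alpha (Var = mu + alpha mu^2); covers biological
        subject-to-subject variability.
    ds_fraction / ds_effect
        Fraction of eligible exons (genes with >=2 exons) given a usage
        shift per time-point comparison, and the |log2| shift applied to
        the exon's softmax weight (sign random).
    de_fraction / de_effect
        As above for gene-level expression fold changes.
    shared_fraction
        Fraction of planted effects present in every cohort; the rest are
        assigned to a single random cohort.
    run_factors
        Library-size multiplier per technical run, recycled.
    """

    depth: float = 5e6
    dispersion: float = 0.05
    gene_logmean_sd: float = 1.0
    exon_weight_sd: float = 0.5
    ds_fraction: float = 0.0
    ds_effect: float = 1.5
    de_fraction: float = 0.0
    de_effect: float = 1.0
    shared_fraction: float = 0.5
    run_factors: tuple[float, ...] = (1.0, 0.8)
    libsize_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name in ("ds_fraction", "de_fraction", "shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass
class SimTruth:
    """Ground truth of every planted effect, keyed by (cohort, comparison).

    ``ds_exons``/``de_genes`` hold the *planted* log2 effects.  Because
    exon usage is compositional (within-gene shares sum to 1), planting
    a shift on one exon also moves its siblings' this-exon-vs-rest
    usage; ``true_usage_shift`` records the exact generative log2
    usage-odds change for every exon, planted or induced, so recovery
    can be scored against what truly changed.
    """

    ds_exons: dict[AnalysisKey, dict[str, float]] = field(default_factory=dict)
    de_genes: dict[AnalysisKey, dict[str, float]] = field(default_factory=dict)
    true_usage_shift: dict[AnalysisKey, dict[str, float]] = field(default_factory=dict)
    enriched_introns: list[GenomicInterval] = field(default_factory=list)
    seed: int | None = None

    def all_ds_exons(self) -> set[str]:
        out: set[str] = set()
        for d in self.ds_exons.values():
            out |= set(d)
        return out

    def shifted_exons(self, key: AnalysisKey, min_abs_log2: float = 1e-6) -> set[str]:
        """Exons whose true usage odds changed by more than ``min_abs_log2``."""
        return {
            e
            for e, v in self.true_usage_shift.get(key, {}).items()
            if abs(v) > min_abs_log2
        }


@dataclass
class SNPSet:
    """Point variants as (chrom, 0-based position) records."""

    records: list[tuple[str, int]]
    label: str = "snps"

    def __post_init__(self) -> None:
        if any(p < 0 for _, p in self.records):
            raise ValueError("SNP positions must be non-negative")
        if len(set(self.records)) != len(self.records):
            raise ValueError("SNP records must be unique")

    def __len__(self) -> int:
        return len(self.records)


def simulate_gene_models(
    n_genes: int,
    exons_per_gene_range: tuple[int, int] = (2, 8),
    exon_len_range: tuple[int, int] = (50, 300),
    intron_len_range: tuple[int, int] = (200, 2000),
    seed: int = 0,
    genes_per_chrom: int = 100,
    intergenic_range: tuple[int, int] = (1000, 5000),
) -> list[GeneModel]:
    """Lay out non-overlapping genes on synthetic chromosomes.

    Ranges are inclusive on both ends.  Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for name, rng_ in (
        ("exons_per_gene_range", exons_per_gene_range),
        ("exon_len_range", exon_len_range),
        ("intron_len_range", intron_len_range),
        ("intergenic_range", intergenic_range),
    ):
        if rng_[0] <= 0 or rng_[1] < rng_[0]:
            raise ValueError(f"{name} must be positive and ordered, got {rng_}")

    rng = np.random.default_rng(seed)
    models: list[GeneModel] = []
    cursor = 0
    width = max(3, len(str(n_genes)))
    for i in range(n_genes):
        chrom_idx = i // genes_per_chrom
        chrom = f"chr{chrom_idx + 1}"
        if i % genes_per_chrom == 0:
            cursor = int(rng.integers(intergenic_range[0], intergenic_range[1] + 1))
        n_exons = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
        exons = []
        pos = cursor
        for j in range(n_exons):
            elen = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + elen))
            pos += elen
            if j < n_exons - 1:
                pos += int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            GeneModel(gene_id=f"G{i + 1:0{width}d}", chrom=chrom, strand=strand, exons=exons)
        )
        cursor = pos + int(rng.integers(intergenic_range[0], intergenic_range[1] + 1))
    return models


def _plant_effects(
    rng: np.random.Generator,
    feature_ids: list[str],
    design: StudyDesign,
    fraction: float,
    effect: float,
    shared_fraction: float,
) -> dict[AnalysisKey, dict[str, float]]:
    """Pick features per comparison and assign signed log2 effects."""
    out: dict[AnalysisKey, dict[str, float]] = {
        (c, comp): {} for c in design.cohorts for comp in design.comparisons
    }
    available = list(feature_ids)
    for comp in design.comparisons:
        n_planted = int(round(fraction * len(feature_ids)))
        n_planted = min(n_planted, len(available))
        if n_planted == 0:
            continue
        chosen = list(rng.choice(len(available), size=n_planted, replace=False))
        chosen_ids = [available[i] for i in sorted(chosen)]
        available = [f for i, f in enumerate(available) if i not in set(chosen)]
        for fid in chosen_ids:
            delta = effect if rng.random() < 0.5 else -effect
            if rng.random() < shared_fraction:
                cohorts = design.cohorts
            else:
                cohorts = (design.cohorts[int(rng.integers(len(design.cohorts)))],)
            for c in cohorts:
                out[(c, comp)][fid] = delta
    return out


def simulate_counts(
    models: list[GeneModel],
    design: StudyDesign | None = None,
    params: SimParams | None = None,
    seed: int = 0,
) -> tuple[ExonCountTable, SimTruth]:
    """Draw NB exon counts for the full design and record planted truth.

    A planted usage effect for comparison (tA, tB) multiplies the exon's
    within-gene weight by 2**delta from tB onwards (so it is visible in
    exactly one consecutive-pair contrast); expression effects behave the
    same on gene means.  Technical runs are independent NB draws around
    the shared subject x timepoint mean times the run's library factor.
    """
    design = design or StudyDesign()
    params = params or SimParams()
    rng = np.random.default_rng(seed)

    gene_ids = [m.gene_id for m in models]
    exon_rows: list[tuple[str, str, int]] = []  # exon_id, gene_id, n_exons_in_gene
    for m in models:
        for i in range(m.n_exons):
            exon_rows.append((m.exon_id(i), m.gene_id, m.n_exons))
    exon_ids = [r[0] for r in exon_rows]
    exon_gene = [r[1] for r in exon_rows]
    eligible = [eid for eid, _, n in exon_rows if n >= 2]

    # gene baseline expression and exon base weights
    theta = rng.lognormal(mean=0.0, sigma=params.gene_logmean_sd, size=len(models))
    theta = theta / theta.sum()
    base_w = rng.lognormal(mean=0.0, sigma=params.exon_weight_sd, size=len(exon_rows))

    truth = SimTruth(seed=seed)
    truth.ds_exons = _plant_effects(
        rng, eligible, design, params.ds_fraction, params.ds_effect, params.shared_fraction
    )
    truth.de_genes = _plant_effects(
        rng, gene_ids, design, params.de_fraction, params.de_effect, params.shared_fraction
    )

    tp_index = {t: i for i, t in enumerate(design.timepoints)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    exon_index = {e: i for i, e in enumerate(exon_ids)}
    gene_of_exon = np.array([gene_index[g] for g in exon_gene])

    # per cohort x timepoint: gene log2 multipliers and exon log2 weight shifts
    n_tp = len(design.timepoints)
    meta = design.sample_table()
    cols = {}
    for c in design.cohorts:
        gene_shift = np.zeros((n_tp, len(models)))
        exon_shift = np.zeros((n_tp, len(exon_rows)))
        for (cc, (tA, tB)), effects in truth.de_genes.items():
            if cc != c:
                continue
            onset = tp_index[tB]
            for gid, d in effects.items():
                gene_shift[onset:, gene_index[gid]] += d
        for (cc, (tA, tB)), effects in truth.ds_exons.items():
            if cc != c:
                continue
            onset = tp_index[tB]
            for eid, d in effects.items():
                exon_shift[onset:, exon_index[eid]] += d
        shares = np.empty((n_tp, len(exon_rows)))
        for ti, t in enumerate(design.timepoints):
            w = base_w * np.exp2(exon_shift[ti])
            # softmax within gene: share = w / gene-sum(w)
            gene_w = np.zeros(len(models))
            np.add.at(gene_w, gene_of_exon, w)
            share = w / gene_w[gene_of_exon]
            shares[ti] = share
            gmean = params.depth * theta * np.exp2(gene_shift[ti])
            mu_bio = gmean[gene_of_exon] * share
            cols[(c, t)] = mu_bio
        # exact generative usage shift (log2 odds of this-exon vs rest)
        multi = np.array([n >= 2 for _, _, n in exon_rows])
        with np.errstate(divide="ignore"):
            odds = np.log2(shares) - np.log2(1.0 - np.where(multi, shares, 0.5))
        for tA, tB in design.comparisons:
            d = odds[tp_index[tB]] - odds[tp_index[tA]]
            truth.true_usage_shift[(c, (tA, tB))] = {
                exon_ids[i]: float(d[i])
                for i in np.nonzero(multi & (np.abs(d) > 1e-12))[0]
            }

    count_cols = {}
    for _, row in meta.iterrows():
        mu_bio = cols[(row["cohort"], row["timepoint"])]
        run_idx = int(row["run"].removeprefix("run")) - 1
        rf = params.run_factors[run_idx % len(params.run_factors)]
        jitter = rng.lognormal(mean=0.0, sigma=params.libsize_jitter_sd)
        mu = np.maximum(mu_bio * rf * jitter, 1e-12)
        lam = rng.gamma(shape=1.0 / params.dispersion, scale=params.dispersion * mu)
        count_cols[row["sample"]] = rng.poisson(lam)

    counts = pd.DataFrame(count_cols, index=pd.Index(exon_ids, name="exon_id"))
    table = ExonCountTable(
        counts=counts,
        gene_ids=pd.Series(exon_gene, index=counts.index, name="gene_id"),
        samples=meta,
    )
    return table, truth


def simulate_snps(
    models: list[GeneModel],
    n_background_snps: int,
    spike_introns: list[GenomicInterval] | None = None,
    n_spiked: int = 0,
    seed: int = 0,
    label: str = "snps",
    truth: SimTruth | None = None,
) -> tuple[SNPSet, SimTruth]:
    """Uniform background SNPs plus SNPs spiked into chosen introns.

    ``spike_introns`` must be introns derivable from ``models``; spiked
    positions are drawn uniformly within a round-robin over those
    introns so every spike interval receives SNPs.
    """
    spike_introns = spike_introns or []
    all_introns = {
        (iv.chrom, iv.start, iv.end) for m in models for iv in m.introns()
    }
    for iv in spike_introns:
        if (iv.chrom, iv.start, iv.end) not in all_introns:
            raise ValueError(f"spike interval {iv} is not an intron of any model")
    if n_spiked > 0 and not spike_introns:
        raise ValueError("n_spiked > 0 requires spike_introns")

    rng = np.random.default_rng(seed)
    chrom_span: dict[str, int] = {}
    for m in models:
        chrom_span[m.chrom] = max(chrom_span.get(m.chrom, 0), m.span.end + 1000)
    chroms = sorted(chrom_span)
    spans = np.array([chrom_span[c] for c in chroms], dtype=float)
    probs = spans / spans.sum()

    records: set[tuple[str, int]] = set()
    guard = 0
    while len(records) < n_background_snps:
        need = n_background_snps - len(records)
        ci = rng.choice(len(chroms), size=need, p=probs)
        pos = rng.integers(0, spans[ci].astype(np.int64))
        records |= set(zip((chroms[i] for i in ci), (int(p) for p in pos)))
        guard += 1
        if guard > 100:
            raise RuntimeError("could not place the requested number of unique SNPs")

    for k in range(n_spiked):
        iv = spike_introns[k % len(spike_introns)]
        for _ in range(100):
            p = int(rng.integers(iv.start, iv.end))
            if (iv.chrom, p) not in records:
                records.add((iv.chrom, p))
                break
        else:
            raise RuntimeError(f"intron {iv} too small for the requested spikes")

    truth = truth or SimTruth(seed=seed)
    truth.enriched_introns = list(spike_introns)
    snps = SNPSet(records=sorted(records), label=label)
    return snps, truth
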