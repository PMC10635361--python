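"""SNP enrichment in flanking introns of differentially spliced exons.

For a set of exons of interest, the observed statistic is the number of
distinct flanking introns (the intronic intervals immediately upstream
and downstream of each exon within its gene model) that contain at least
one SNP.  The null distribution comes from 1000 control exon sets of the
same size sampled uniformly without replacement from all tested exons.
An observed value above the 95th empirical percentile of the null is
called enriched, below the 5th depleted, otherwise not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GeneModel, GenomicInterval, exon_index_map
from .simulate import SNPSet

ENRICHED_CUT = 0.95
DEPLETED_CUT = 0.05


@dataclass
class EnrichmentResult:
    observed: int
    null_counts: np.ndarray
    empirical_percentile: float
    call: str  # enriched | depleted | ns
    n_perm: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.null_counts) != self.n_perm:
            raise ValueError("null_counts length must equal n_perm")


def flanking_introns(model: GeneModel, exon_index: int) -> list[GenomicInterval]:
    """Up to two intronic intervals adjacent to the exon (strandless).

    For exon i: upstream flank [end(exon_{i-1}), start(exon_i)) and
    downstream flank [end(exon_i), start(exon_{i+1})).  Terminal exons
    yield one flank; single-exon genes none.  Zero-length gaps between
    abutting exons yield no flank.
    """
    if not 0 <= exon_index < model.n_exons:
        raise IndexError(f"exon index {exon_index} invalid for {model.gene_id}")
    flanks = []
    e = model.exons[exon_index]
    if exon_index > 0:
        prev = model.exons[exon_index - 1]
        if prev.end < e.start:
            flanks.append(GenomicInterval(model.chrom, prev.end, e.start))
    if exon_index < model.n_exons - 1:
        nxt = model.exons[exon_index + 1]
        if e.end < nxt.start:
            flanks.append(GenomicInterval(model.chrom, e.end, nxt.start))
    return flanks


def count_intron_hits(flanks: list[GenomicInterval], snps: SNPSet) -> int:
    """Distinct intron intervals containing at least one SNP.

    A SNP at position p hits [a, b) iff a <= p < b on the same
    chromosome.  Introns are deduplicated by identical coordinates only
    (adjacent exons naming the same intron count it once); an intron
    with many SNPs counts once.
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in snps.records:
        by_chrom.setdefault(chrom, []).append(pos)
    sorted_pos = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    seen = set()
    hits = 0
    for iv in flanks:
        key = (iv.chrom, iv.start, iv.end)
        if key in seen:
            continue
        seen.add(key)
        pos = sorted_pos.get(iv.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        if hi > lo:
            hits += 1
    return hits


class _FlankIndex:
    """Precomputed exon -> flank-interval ids with per-flank SNP hits.

    Lets the 1000-permutation null be computed as unions of integer id
    sets instead of repeated interval intersections.
    """

    def __init__(self, models: list[GeneModel], exon_ids: list[str], snps: SNPSet):
        emap = exon_index_map(models)
        flank_ids: dict[tuple[str, int, int], int] = {}
        per_exon: list[np.ndarray] = []
        flank_list: list[GenomicInterval] = []
        for eid in exon_ids:
            if eid not in emap:
                raise KeyError(f"exon id {eid!r} not found in the gene models")
            model, idx = emap[eid]
            ids = []
            for iv in flanking_introns(model, idx):
                key = (iv.chrom, iv.start, iv.end)
                if key not in flank_ids:
                    flank_ids[key] = len(flank_ids)
                    flank_list.append(iv)
                ids.append(flank_ids[key])
            per_exon.append(np.asarray(ids, dtype=np.int64))
        self.per_exon = per_exon
        hit = np.zeros(len(flank_list), dtype=bool)
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in snps.records:
            by_chrom.setdefault(chrom, []).append(pos)
        sorted_pos = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
        for fid, iv in enumerate(flank_list):
            pos = sorted_pos.get(iv.chrom)
            if pos is None:
                continue
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="left")
            hit[fid] = hi > lo
        self.hit = hit

    def count(self, exon_indices: np.ndarray) -> int:
        ids = (
            np.unique(np.concatenate([self.per_exon[i] for i in exon_indices]))
            if len(exon_indices)
            else np.empty(0, dtype=np.int64)
        )
        return int(self.hit[ids].sum())


def permutation_enrichment(
    ds_exons: list[str] | set[str],
    tested_exons: list[str],
    models: list[GeneModel],
    snps: SNPSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Matched-size permutation test of SNP density in flanking introns.

    The empirical percentile is the fraction of null counts strictly
    below the observed count (ties count against enrichment).
    """
    tested = sorted(set(tested_exons))
    ds = sorted(set(ds_exons))
    missing = set(ds) - set(tested)
    if missing:
        raise ValueError(
            f"{len(missing)} differentially spliced exons not among tested exons"
        )
    index = _FlankIndex(models, tested, snps)
    pos_of = {e: i for i, e in enumerate(tested)}
    ds_idx = np.asarray([pos_of[e] for e in ds], dtype=np.int64)
    observed = index.count(ds_idx)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    n = len(tested)
    k = len(ds)
    for i in range(n_perm):
        null[i] = index.count(rng.choice(n, size=k, replace=False))
    percentile = float((null < observed).mean())
    frac_above = float((null > observed).mean())
    # ties count against significance in both directions, so a degenerate
    # null (every count equal to the observed) is "ns", not depleted
    if percentile > ENRICHED_CUT:
        call = "enriched"
    elif frac_above > ENRICHED_CUT:
        call = "depleted"
    else:
        call = "ns"
    return EnrichmentResult(
        observed=int(observed),
        null_counts=null,
        empirical_percentile=percentile,
        call=call,
        n_perm=n_perm,
        seed=seed,
    )
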