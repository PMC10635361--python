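import numpy as np
import pandas as pd
import pytest

from splicedyn.intervals import GeneModel, GenomicInterval
from splicedyn.simulate import (
    SimParams,
    StudyDesign,
    simulate_counts,
    simulate_gene_models,
)


@pytest.fixture(scope="session")
def small_models():
    """200 four-exon genes, the layout used by the calibration checks."""
    return simulate_gene_models(200, exons_per_gene_range=(4, 4), seed=1)


@pytest.fixture(scope="session")
def null_table(small_models):
    """Counts with no planted effects."""
    table, truth = simulate_counts(small_models, StudyDesign(), SimParams(), seed=42)
    return table, truth


@pytest.fixture()
def three_exon_gene():
    return GeneModel(
        gene_id="G1",
        chrom="chr1",
        strand="+",
        exons=[
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 300, 400),
            GenomicInterval("chr1", 500, 600),
        ],
    )


@pytest.fixture()
def tiny_count_table():
    """Two genes x three exons, 4+4 samples, constant usage shares."""
    from splicedyn.counts import ExonCountTable

    rng = np.random.default_rng(0)
    meta = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(8)],
            "cohort": ["lean"] * 8,
            "timepoint": ["confluence"] * 4 + ["day3"] * 4,
            "subject": [f"p{i}" for i in range(8)],
            "run": ["run1", "run2"] * 4,
        }
    )
    exon_ids = [f"G{g}:E{e:03d}" for g in (1, 2) for e in (1, 2, 3)]
    gene_ids = [f"G{g}" for g in (1, 2) for _ in range(3)]
    shares = np.array([0.2, 0.3, 0.5, 0.25, 0.25, 0.5])
    depth = 5000.0
    mu = shares * depth
    counts = rng.poisson(np.tile(mu[:, None], (1, 8)))
    df = pd.DataFrame(counts, index=pd.Index(exon_ids, name="exon_id"),
                      columns=meta["sample"].tolist())
    return ExonCountTable(
        counts=df,
        gene_ids=pd.Series(gene_ids, index=df.index),
        samples=meta,
    )
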