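"""Exon-level count table with attached sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: required sample-metadata columns
META_COLUMNS = ("sample", "cohort", "timepoint", "subject", "run")


@dataclass
class ExonCountTable:
    """Integer exon counts (exons x samples) grouped by gene.

    ``counts`` is indexed by exon id with one column per sample;
    ``gene_ids`` is a parallel Series mapping exon id -> gene id;
    ``samples`` holds one metadata row per count column (cohort,
    timepoint, subject, run).
    """

    counts: pd.DataFrame
    gene_ids: pd.Series
    samples: pd.DataFrame
    testable: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_ids.index):
            raise ValueError("counts and gene_ids must share the same exon index")
        missing = set(META_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        if list(self.counts.columns) != list(self.samples["sample"]):
            raise ValueError("count columns must match metadata 'sample' order")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
        if self.testable is None:
            self.testable = pd.Series(True, index=self.counts.index)

    @property
    def exon_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_exons(self) -> int:
        return len(self.counts)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def gene_totals(self) -> pd.DataFrame:
        """Per-gene count sums over exons (genes x samples)."""
        return self.counts.groupby(self.gene_ids).sum()

    def subset_samples(self, mask: pd.Series | np.ndarray) -> "ExonCountTable":
        meta = self.samples.loc[np.asarray(mask)].reset_index(drop=True)
        return ExonCountTable(
            counts=self.counts[meta["sample"].tolist()],
            gene_ids=self.gene_ids,
            samples=meta,
            testable=self.testable.copy(),
        )

    def select(
        self,
        cohort: str | None = None,
        timepoints: tuple[str, ...] | None = None,
    ) -> "ExonCountTable":
        mask = np.ones(len(self.samples), dtype=bool)
        if cohort is not None:
            mask &= (self.samples["cohort"] == cohort).to_numpy()
        if timepoints is not None:
            mask &= self.samples["timepoint"].isin(timepoints).to_numpy()
        if not mask.any():
            raise ValueError(
                f"no samples match cohort={cohort!r}, timepoints={timepoints!r}"
            )
        return self.subset_samples(mask)
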