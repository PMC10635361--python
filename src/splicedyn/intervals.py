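"""Genomic intervals and gene models.

Coordinates are 0-based half-open throughout the package (the BED
convention).  GFF3 output converts to 1-based inclusive at the boundary;
see :mod:`splicedyn.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether a point (0-based) falls inside the interval."""
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene as an ordered set of non-overlapping exons on one chromosome.

    Exons are stored in ascending start order regardless of strand; exon
    indices used elsewhere in the package refer to this genomic order.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping exons in gene {self.gene_id}: {a} and {b}"
                )
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"exon chromosome {e.chrom} differs from gene {self.chrom}"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    def exon_id(self, index: int) -> str:
        """Stable exon identifier: ``<gene_id>:E<index+1, zero-padded>``."""
        if not 0 <= index < self.n_exons:
            raise IndexError(f"exon index {index} out of range for {self.gene_id}")
        return f"{self.gene_id}:E{index + 1:03d}"

    def introns(self) -> list[GenomicInterval]:
        """Intervals between consecutive exons (empty for single-exon genes)."""
        return [
            GenomicInterval(self.chrom, a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
            if a.end < b.start
        ]

    def iter_exon_ids(self) -> Iterator[str]:
        for i in range(self.n_exons):
            yield self.exon_id(i)


def exon_index_map(models: Sequence[GeneModel]) -> dict[str, tuple[GeneModel, int]]:
    """Map every exon id to its (gene model, exon index)."""
    out: dict[str, tuple[GeneModel, int]] = {}
    for m in models:
        for i in range(m.n_exons):
            out[m.exon_id(i)] = (m, i)
    return out
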