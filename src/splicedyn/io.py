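"""Readers and writers for the flat-file interfaces.

Dialects: counts and metadata are TSV; flattened annotation is GFF3 with
one ``exonic_part`` record per exon (1-based inclusive coordinates on
disk, converted to the package's internal 0-based half-open convention
on read); SNPs are 3-column BED (0-based half-open, written as-is) or
1-based TSV; planted truth is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import ExonCountTable
from .intervals import GeneModel, GenomicInterval
from .simulate import SimTruth, SNPSet


def write_counts(table: ExonCountTable, counts_path: Path, meta_path: Path) -> None:
    out = table.counts.copy()
    out.insert(0, "gene_id", table.gene_ids)
    out.to_csv(counts_path, sep="\t", index_label="exon_id")
    table.samples.to_csv(meta_path, sep="\t", index=False)


def read_counts(counts_path: Path, meta_path: Path) -> ExonCountTable:
    df = pd.read_csv(counts_path, sep="\t", index_col="exon_id")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    gene_ids = df.pop("gene_id")
    return ExonCountTable(counts=df, gene_ids=gene_ids, samples=meta)


def write_gff3(models: list[GeneModel], path: Path) -> None:
    """Flattened annotation: one gene and one exonic_part row per exon."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            fh.write(
                f"{m.chrom}\tsplicedyn\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            for i, e in enumerate(m.exons):
                fh.write(
                    f"{m.chrom}\tsplicedyn\texonic_part\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.strand}\t.\tParent={m.gene_id};exonic_part_number={i + 1:03d};"
                    f"ID={m.exon_id(i)}\n"
                )


def read_gff3(path: Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = fields["ID"]
                genes[gid] = {"chrom": chrom, "strand": strand, "exons": []}
                order.append(gid)
            elif ftype == "exonic_part":
                gid = fields["Parent"]
                genes[gid]["exons"].append(
                    GenomicInterval(chrom, int(start) - 1, int(end))
                )
    return [
        GeneModel(gene_id=g, chrom=genes[g]["chrom"], strand=genes[g]["strand"],
                  exons=genes[g]["exons"])
        for g in order
    ]


def write_bed(snps: SNPSet, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in snps.records:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{snps.label}\n")


def read_snps(path: Path, dialect: str = "bed") -> SNPSet:
    """Read SNPs from 0-based BED or 1-based two-column TSV."""
    records: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.split()
            if dialect == "bed":
                records.append((parts[0], int(parts[1])))
            elif dialect == "tsv1":
                records.append((parts[0], int(parts[1]) - 1))
            else:
                raise ValueError(f"unknown SNP dialect {dialect!r}")
    return SNPSet(records=sorted(set(records)), label=Path(path).stem)


def write_truth(truth: SimTruth, path: Path) -> None:
    doc = {
        "seed": truth.seed,
        "ds_exons": {
            f"{c}|{a}|{b}": effects
            for (c, (a, b)), effects in truth.ds_exons.items()
            if effects
        },
        "de_genes": {
            f"{c}|{a}|{b}": effects
            for (c, (a, b)), effects in truth.de_genes.items()
            if effects
        },
        "enriched_introns": [
            [iv.chrom, iv.start, iv.end] for iv in truth.enriched_introns
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_truth(path: Path) -> SimTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def parse(d: dict) -> dict:
        out = {}
        for key, effects in (d or {}).items():
            c, a, b = key.split("|")
            out[(c, (a, b))] = {k: float(v) for k, v in effects.items()}
        return out

    return SimTruth(
        ds_exons=parse(doc.get("ds_exons")),
        de_genes=parse(doc.get("de_genes")),
        enriched_introns=[
            GenomicInterval(c, int(s), int(e))
            for c, s, e in doc.get("enriched_introns", [])
        ],
        seed=doc.get("seed"),
    )


def write_json(obj, path: Path) -> None:
    """Deterministic JSON (sorted keys, no timestamps) for manifests."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
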