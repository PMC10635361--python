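"""End-to-end orchestration: simulate -> DEU/DGE -> sharing -> clustering
-> GWAS enrichment, driven by one YAML config with per-stage seeds.

Every stage writes its outputs under a run directory; a manifest records
input file hashes, seeds and the package version so a rerun with the
same config is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    assign_and_prevalence,
    center_scale,
    fuzzy_cmeans,
    match_clusters_across_cohorts,
    select_cluster_input,
)
from .counts import ExonCountTable
from .exon_usage import (
    ExonUsageResult,
    filter_testable,
    test_exon_usage,
    test_gene_expression,
    usage_coefficients,
)
from .gwas import permutation_enrichment
from .intervals import GeneModel
from .io import (
    read_counts,
    read_gff3,
    read_snps,
    write_bed,
    write_counts,
    write_gff3,
    write_json,
    write_truth,
)
from .sharing import build_effect_matrix, sharing_matrix
from .simulate import (
    SimParams,
    SimTruth,
    SNPSet,
    StudyDesign,
    simulate_counts,
    simulate_gene_models,
    simulate_snps,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    outdir: Path
    n_genes: int = 50
    design: StudyDesign = field(default_factory=StudyDesign)
    sim: SimParams = field(default_factory=SimParams)
    min_total: int = 10
    fdr: float = 0.05
    fold_change: float = 1.25
    sharing_factor: float = 0.5
    k: int = 6
    fuzzifier: float = 2.0
    n_perm: int = 1000
    n_background_snps: int = 500
    n_spiked_snps: int = 0
    seeds: dict[str, int] = field(default_factory=dict)
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if not 0 < self.sharing_factor <= 1:
            raise ValueError("sharing_factor must lie in (0, 1]")
        if self.k < 1 or self.n_perm < 1:
            raise ValueError("k and n_perm must be >= 1")
        defaults = {"simulate": 1, "snps": 2, "clustering": 3, "enrichment": 4}
        self.seeds = {**defaults, **self.seeds}

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        design = StudyDesign(
            cohorts=tuple(doc.get("cohorts", StudyDesign.cohorts)),
            timepoints=tuple(doc.get("timepoints", StudyDesign.timepoints)),
            subjects_per_cohort=doc.get("subjects_per_cohort", 3),
            runs_per_sample=doc.get("runs_per_sample", 2),
        )
        sim = SimParams(**doc.get("sim", {}))
        keys = {
            k: doc[k]
            for k in (
                "n_genes", "min_total", "fdr", "fold_change", "sharing_factor",
                "k", "fuzzifier", "n_perm", "n_background_snps", "n_spiked_snps",
                "make_plots",
            )
            if k in doc
        }
        return cls(
            outdir=Path(doc.get("outdir", "splicedyn_run")),
            design=design,
            sim=sim,
            seeds=doc.get("seeds", {}),
            **keys,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the summary dict (also written to disk).

    Raises with a stage-attributed message on the first failing stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"version": __version__, "seeds": config.seeds,
                                "files": {}}
    summary: dict[str, Any] = {}

    stage = "simulate"
    try:
        models = simulate_gene_models(config.n_genes, seed=config.seeds["simulate"])
        table, truth = simulate_counts(
            models, config.design, config.sim, seed=config.seeds["simulate"]
        )
        # spike SNPs into flanks of exons with planted usage shifts in the
        # first (early-differentiation) comparison, so the enrichment stage
        # has a real signal to find
        spike: list = []
        if config.n_spiked_snps:
            from .gwas import flanking_introns
            from .intervals import exon_index_map

            emap = exon_index_map(models)
            first_comp = config.design.comparisons[0]
            early_ds = sorted(
                {
                    e
                    for (c, comp), eff in truth.ds_exons.items()
                    if comp == first_comp
                    for e in eff
                }
            )
            seen: dict = {}
            for e in early_ds:
                gm, idx = emap[e]
                for iv in flanking_introns(gm, idx):
                    seen[(iv.chrom, iv.start, iv.end)] = iv
            spike = list(seen.values())
        snps, truth = simulate_snps(
            models,
            config.n_background_snps,
            spike_introns=spike,
            n_spiked=config.n_spiked_snps,
            seed=config.seeds["snps"],
            truth=truth,
        )
        write_gff3(models, out / "models.gff3")
        write_counts(table, out / "counts.tsv", out / "samples.tsv")
        write_bed(snps, out / "snps.bed")
        write_truth(truth, out / "truth.yaml")
        summary["simulate"] = {
            "n_genes": len(models),
            "n_exons": table.n_exons,
            "n_samples": table.n_samples,
            "n_snps": len(snps),
        }
    except Exception as exc:  # noqa: BLE001 - reattributed below
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "exon_usage"
    try:
        table = filter_testable(table, min_total=config.min_total)
        deu_results: list[ExonUsageResult] = []
        dge_results = []
        for cohort in config.design.cohorts:
            for comp in config.design.comparisons:
                r = test_exon_usage(table, cohort, comp)
                name = f"deu_{cohort}_{comp[0]}_vs_{comp[1]}.tsv"
                r.table.to_csv(out / name, sep="\t")
                deu_results.append(r)
                g = test_gene_expression(table, cohort, comp)
                g.table.to_csv(out / f"dge_{cohort}_{comp[0]}_vs_{comp[1]}.tsv", sep="\t")
                dge_results.append(g)
        summary["exon_usage"] = {
            f"{r.cohort}:{r.comparison[0]}-vs-{r.comparison[1]}": int(
                len(r.significant_exons)
            )
            for r in deu_results
        }
        summary["expression"] = {
            f"{g.cohort}:{g.comparison[0]}-vs-{g.comparison[1]}": int(
                len(g.significant_genes)
            )
            for g in dge_results
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "sharing"
    try:
        splicing_m = build_effect_matrix(splicing=deu_results)
        sm_spl = sharing_matrix(splicing_m, factor=config.sharing_factor)
        sm_spl.fractions.to_csv(out / "sharing_splicing.tsv", sep="\t")
        expr_m = build_effect_matrix(expression=dge_results)
        sm_expr = sharing_matrix(expr_m, factor=config.sharing_factor)
        sm_expr.fractions.to_csv(out / "sharing_expression.tsv", sep="\t")
        cross_m = build_effect_matrix(
            splicing=deu_results, expression=dge_results, gene_level=True
        )
        sm_cross = sharing_matrix(cross_m, factor=config.sharing_factor)
        sm_cross.fractions.to_csv(out / "sharing_cross.tsv", sep="\t")
        summary["sharing"] = {
            "splicing_mean": _offdiag_mean(sm_spl.fractions),
            "expression_mean": _offdiag_mean(sm_expr.fractions),
            "cross_mean": _offdiag_mean(sm_cross.fractions),
        }
        if config.make_plots:
            from .plotting import plot_sharing_heatmap

            plot_sharing_heatmap(sm_spl, out / "sharing_splicing.png", "splicing")
            plot_sharing_heatmap(sm_expr, out / "sharing_expression.png", "expression")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "clustering"
    try:
        cluster_models = {}
        summary["clustering"] = {}
        for cohort in config.design.cohorts:
            chosen = select_cluster_input(deu_results, cohort)
            if len(chosen) < config.k:
                logger.warning(
                    "cohort %s: %d significant exons < k=%d, skipping clustering",
                    cohort, len(chosen), config.k,
                )
                continue
            coefs = usage_coefficients(table, cohort)
            traj = center_scale(coefs.loc[sorted(set(chosen) & set(coefs.index))])
            model = fuzzy_cmeans(
                traj, k=config.k, m=config.fuzzifier, seed=config.seeds["clustering"]
            )
            assign = assign_and_prevalence(model)
            cluster_models[cohort] = model
            model.membership.to_csv(out / f"membership_{cohort}.tsv", sep="\t")
            assign.assignments.to_csv(out / f"clusters_{cohort}.tsv", sep="\t")
            pd.DataFrame(
                model.centroids, columns=list(coefs.columns)
            ).to_csv(out / f"centroids_{cohort}.tsv", sep="\t")
            summary["clustering"][cohort] = {
                "n_exons": int(len(assign.assignments)),
                "prevalence_pct": [round(float(v), 4) for v in assign.prevalence],
            }
            if config.make_plots:
                from .plotting import plot_cluster_trajectories

                plot_cluster_trajectories(
                    model, assign, traj, out / f"clusters_{cohort}.png"
                )
        if len(cluster_models) >= 2:
            match = match_clusters_across_cohorts(cluster_models)
            match.to_csv(out / "cluster_matching.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "gwas_enrichment"
    try:
        summary["gwas_enrichment"] = {}
        for r in deu_results:
            tested = list(r.table.index[r.table["tested"].fillna(False)])
            ds = list(r.significant_exons)
            key = f"{r.cohort}:{r.comparison[0]}-vs-{r.comparison[1]}"
            if not ds:
                summary["gwas_enrichment"][key] = {"call": "ns", "observed": 0,
                                                   "percentile": None}
                continue
            enr = permutation_enrichment(
                ds, tested, models, snps,
                n_perm=config.n_perm, seed=config.seeds["enrichment"],
            )
            summary["gwas_enrichment"][key] = {
                "observed": enr.observed,
                "percentile": round(enr.empirical_percentile, 6),
                "call": enr.call,
            }
            if config.make_plots:
                from .plotting import plot_null_histogram

                plot_null_histogram(
                    enr, out / f"enrichment_{key.replace(':', '_')}.png", key
                )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.suffix in (".tsv", ".gff3", ".bed", ".yaml"):
            manifest["files"][f.name] = _sha256(f)
    write_json(manifest, out / "manifest.json")
    write_json(summary, out / "summary.json")
    return summary


def _offdiag_mean(df: pd.DataFrame) -> float | None:
    a = df.to_numpy(float).copy()
    np.fill_diagonal(a, np.nan)
    vals = a[np.isfinite(a)]
    return round(float(vals.mean()), 6) if vals.size else None
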