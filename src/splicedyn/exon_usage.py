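"""Differential exon usage (DEU) and gene-level differential expression (DGE).

The DEU estimand is the change, between two conditions, in the share of a
gene's reads that fall on one exon, independent of the gene's overall
expression.  Each testable exon is modelled as a two-bin negative-binomial
GLM on the pair (this exon, sum of the gene's other exons): with log link,

    log mu = b0 + b_bin * bin + b_cond * cond + run effects
             + b_int * bin * cond + log(size factor)

where ``bin`` indicates the exon (vs rest-of-gene) and ``cond`` the second
time point.  ``b_int`` is the log usage fold change; its likelihood-ratio
test against the no-interaction model is the DEU p-value.  Technical
sequencing runs enter as a fixed-effect covariate.  Exons with FDR < 0.05
(Benjamini-Hochberg) are called differentially used.

Gene-level differential expression uses a per-gene NB GLM (condition +
run) with a Wald test on the condition coefficient; genes with FDR < 0.05
and fold change >= 1.25 are called differentially expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import ExonCountTable
from .simulate import Comparison
from .stats import (
    bh_fdr,
    estimate_dispersion,
    fit_nb_glm,
    lrt_pvalues,
    size_factors_median_of_ratios,
    wald_pvalues,
)

LN2 = np.log(2.0)
FDR_THRESHOLD = 0.05
DGE_FC_THRESHOLD = 1.25


@dataclass
class ExonUsageResult:
    """Per-exon DEU results for one cohort and time-point comparison.

    ``table`` is indexed by exon id with columns: gene_id, per-time-point
    usage coefficients (``coef_<timepoint>``, natural-log relative usage),
    log2fc (usage log2 fold change tB vs tA), se, z, pvalue, qvalue,
    significant, tested.  Untested exons carry NaN statistics.
    """

    cohort: str
    comparison: Comparison
    table: pd.DataFrame

    @property
    def significant_exons(self) -> pd.Index:
        return self.table.index[self.table["significant"].fillna(False)]


@dataclass
class DGEResult:
    """Per-gene differential-expression results for one comparison."""

    cohort: str
    comparison: Comparison
    table: pd.DataFrame  # index gene_id: log2fc, se, z, pvalue, qvalue, significant

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"].fillna(False)]


def filter_testable(table: ExonCountTable, min_total: int = 10) -> ExonCountTable:
    """Flag low-count exons and usage-untestable exons.

    An exon is testable for usage if its summed count over all samples is
    >= ``min_total`` and its gene retains at least two such exons (the
    this-exon-vs-rest model needs a nonempty rest bin).
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = table.counts.sum(axis=1)
    enough = totals >= min_total
    per_gene = enough.groupby(table.gene_ids).transform("sum")
    testable = enough & (per_gene >= 2)
    return ExonCountTable(
        counts=table.counts,
        gene_ids=table.gene_ids,
        samples=table.samples,
        testable=testable,
    )


def _check_design(sub: ExonCountTable, timepoints: tuple[str, ...]) -> None:
    for t in timepoints:
        sel = sub.samples[sub.samples["timepoint"] == t]
        if sel.empty:
            raise ValueError(f"time point {t!r} absent from the selected samples")
        if sel["subject"].nunique() < 2:
            raise ValueError(f"time point {t!r} has fewer than 2 subjects")


def _run_dummies(meta: pd.DataFrame) -> np.ndarray:
    levels = sorted(meta["run"].unique())
    return np.column_stack(
        [(meta["run"] == lv).to_numpy(float) for lv in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(meta), 0))


def _usage_design(
    meta: pd.DataFrame, timepoints: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stacked two-bin design: rows = [exon-bin samples, rest-bin samples].

    Returns (X_full, X_reduced-column-mask, column names).  Condition and
    bin:condition columns are dummies against the first time point.
    """
    n = len(meta)
    bin_col = np.concatenate([np.ones(n), np.zeros(n)])
    cond = np.column_stack(
        [(meta["timepoint"] == t).to_numpy(float) for t in timepoints[1:]]
    )
    cond2 = np.vstack([cond, cond])
    runs = _run_dummies(meta)
    runs2 = np.vstack([runs, runs])
    inter = bin_col[:, None] * cond2
    X = np.column_stack([np.ones(2 * n), bin_col, cond2, runs2, inter])
    names = (
        ["intercept", "bin"]
        + [f"cond_{t}" for t in timepoints[1:]]
        + [f"run_{i}" for i in range(runs.shape[1])]
        + [f"bin:cond_{t}" for t in timepoints[1:]]
    )
    return X, inter, names


def _stacked_counts(
    sub: ExonCountTable, exon_ids: pd.Index
) -> tuple[np.ndarray, np.ndarray]:
    """(exon counts, rest-of-gene counts) matrices for the chosen exons."""
    E = sub.counts.loc[exon_ids].to_numpy(float)
    gene_tot = sub.gene_totals()
    G = gene_tot.loc[sub.gene_ids.loc[exon_ids]].to_numpy(float)
    return E, G - E


def _fit_usage(
    sub: ExonCountTable,
    timepoints: tuple[str, ...],
) -> tuple[pd.Index, np.ndarray, np.ndarray, "_UsageFit"]:
    """Shared machinery: fit the full two-bin model for all testable exons.

    Dispersion is estimated separately for the exon bin and the
    rest-of-gene bin: the rest bin aggregates several exons, so its
    dispersion is systematically lower, and a single pooled value
    miscalibrates the likelihood-ratio test.
    """
    meta = sub.samples
    exon_ids = sub.exon_ids[sub.testable.to_numpy()]
    if len(exon_ids) == 0:
        raise ValueError("no testable exons in the selected samples")
    E, R = _stacked_counts(sub, exon_ids)
    Y = np.hstack([E, R])  # (exons, 2*n_samples)
    sf = size_factors_median_of_ratios(sub.counts.to_numpy())
    sf2 = np.concatenate([sf, sf])
    X, _, names = _usage_design(meta, timepoints)
    group = (meta["timepoint"].astype(str) + "|" + meta["run"].astype(str)).to_numpy()
    alpha_exon = estimate_dispersion(E / sf, group)
    alpha_rest = estimate_dispersion(R / sf, group)
    alpha = np.hstack(
        [
            np.repeat(alpha_exon[:, None], E.shape[1], axis=1),
            np.repeat(alpha_rest[:, None], R.shape[1], axis=1),
        ]
    )
    full = fit_nb_glm(Y, X, alpha, offset=np.log(sf2))
    reduced_cols = [i for i in range(X.shape[1]) if not names[i].startswith("bin:")]
    red = fit_nb_glm(Y, X[:, reduced_cols], alpha, offset=np.log(sf2))
    return exon_ids, Y, alpha_exon, _UsageFit(X=X, names=names, full=full, reduced=red)


@dataclass
class _UsageFit:
    X: np.ndarray
    names: list[str]
    full: object
    reduced: object


def test_exon_usage(
    table: ExonCountTable, cohort: str, comparison: Comparison
) -> ExonUsageResult:
    """DEU likelihood-ratio test for one cohort and time-point pair."""
    tA, tB = comparison
    sub = table.select(cohort=cohort, timepoints=(tA, tB))
    _check_design(sub, (tA, tB))
    exon_ids, Y, alpha, fit = _fit_usage(sub, (tA, tB))
    names = fit.names
    i_bin = names.index("bin")
    i_int = names.index(f"bin:cond_{tB}")
    beta = fit.full.beta
    p = lrt_pvalues(fit.full.loglik, fit.reduced.loglik, df=1)
    q = bh_fdr(p)
    lfc = beta[:, i_int] / LN2
    se = fit.full.se[:, i_int] / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)

    res = pd.DataFrame(index=table.exon_ids)
    res["gene_id"] = table.gene_ids
    res["tested"] = False
    for col in (f"coef_{tA}", f"coef_{tB}", "log2fc", "se", "z", "pvalue", "qvalue"):
        res[col] = np.nan
    res.loc[exon_ids, "tested"] = True
    res.loc[exon_ids, f"coef_{tA}"] = beta[:, i_bin]
    res.loc[exon_ids, f"coef_{tB}"] = beta[:, i_bin] + beta[:, i_int]
    res.loc[exon_ids, "log2fc"] = lfc
    res.loc[exon_ids, "se"] = se
    res.loc[exon_ids, "z"] = z
    res.loc[exon_ids, "pvalue"] = p
    res.loc[exon_ids, "qvalue"] = q
    res["significant"] = res["qvalue"] < FDR_THRESHOLD
    return ExonUsageResult(cohort=cohort, comparison=(tA, tB), table=res)


def usage_coefficients(table: ExonCountTable, cohort: str) -> pd.DataFrame:
    """Per-exon usage coefficients over all time points from one joint fit.

    Returns a DataFrame (testable exons x time points) of natural-log
    relative-usage coefficients, run covariate included; input to the
    trajectory clustering.
    """
    timepoints = tuple(
        t for t in table.samples["timepoint"].unique()
    )
    sub = table.select(cohort=cohort)
    _check_design(sub, timepoints)
    exon_ids, _, _, fit = _fit_usage(sub, timepoints)
    names = fit.names
    beta = fit.full.beta
    i_bin = names.index("bin")
    coefs = {timepoints[0]: beta[:, i_bin]}
    for t in timepoints[1:]:
        coefs[t] = beta[:, i_bin] + beta[:, names.index(f"bin:cond_{t}")]
    return pd.DataFrame(coefs, index=exon_ids)


def test_gene_expression(
    table: ExonCountTable, cohort: str, comparison: Comparison
) -> DGEResult:
    """Per-gene NB Wald test (condition + run) with the dual DGE rule."""
    tA, tB = comparison
    sub = table.select(cohort=cohort, timepoints=(tA, tB))
    _check_design(sub, (tA, tB))
    meta = sub.samples
    G = sub.gene_totals()
    keep = G.sum(axis=1) > 0
    G = G.loc[keep]
    Y = G.to_numpy(float)
    sf = size_factors_median_of_ratios(sub.counts.to_numpy())
    cond = (meta["timepoint"] == tB).to_numpy(float)
    runs = _run_dummies(meta)
    X = np.column_stack([np.ones(len(meta)), cond, runs])
    group = meta["timepoint"].astype(str) + "|" + meta["run"].astype(str)
    alpha = estimate_dispersion(Y / sf, group.to_numpy())
    fit = fit_nb_glm(Y, X, alpha, offset=np.log(sf))
    beta_c = fit.beta[:, 1]
    se_c = fit.se[:, 1]
    p = wald_pvalues(beta_c, se_c)
    q = bh_fdr(p)
    lfc = beta_c / LN2

    res = pd.DataFrame(index=G.index)
    res["log2fc"] = lfc
    res["se"] = se_c / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        res["z"] = np.where(se_c > 0, beta_c / se_c, 0.0)
    res["pvalue"] = p
    res["qvalue"] = q
    res["significant"] = (res["qvalue"] < FDR_THRESHOLD) & (
        np.abs(res["log2fc"]) >= np.log2(DGE_FC_THRESHOLD)
    )
    res.index.name = "gene_id"
    return DGEResult(cohort=cohort, comparison=(tA, tB), table=res)
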