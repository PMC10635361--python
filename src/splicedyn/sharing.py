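"""Pairwise sharing of significant effects between analyses.

Two analyses (cohort x comparison x modality) share an effect when the
feature is significant (q < 0.05) in at least one of them, the two
estimates have the same sign, and their magnitudes are within a factor
of 0.5 of each other (boundary inclusive).  The sharing fraction is the
proportion of such features among the significant-in-at-least-one set.

Sharing is computed on the estimated effects directly.  The
empirical-Bayes multivariate shrinkage some analyses apply before this
criterion (mashr-style posterior effects) is deliberately not modelled;
see the methods note for the consequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exon_usage import DGEResult, ExonUsageResult

SHARING_FACTOR = 0.5


@dataclass
class EffectMatrix:
    """Features x analyses effects with significance flags.

    ``effects`` and ``significant`` are DataFrames with identical shape;
    features absent from an analysis hold NaN effects and False flags.
    """

    effects: pd.DataFrame
    significant: pd.DataFrame
    zscores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.effects.columns.equals(self.significant.columns):
            raise ValueError("effects and significance flags must share analyses")
        if not self.effects.index.equals(self.significant.index):
            raise ValueError("effects and significance flags must share features")

    @property
    def analyses(self) -> list[str]:
        return list(self.effects.columns)


@dataclass
class SharingMatrix:
    """Symmetric pairwise sharing fractions with denominators."""

    fractions: pd.DataFrame  # NaN where undefined (empty denominator)
    n_denominator: pd.DataFrame


def aggregate_to_gene(res: ExonUsageResult) -> pd.DataFrame:
    """Collapse exon-level DEU results to one row per gene.

    Each gene carries the statistics of its most significant (minimum
    p-value) tested exon; ties are broken by the lexicographically
    smallest exon id.
    """
    t = res.table[res.table["tested"].fillna(False)].copy()
    t = t.sort_index(kind="stable").sort_values("pvalue", kind="stable")
    best = t[~t["gene_id"].duplicated()]
    out = best.reset_index().rename(columns={best.index.name or "index": "exon_id"})
    out = out.set_index("gene_id").sort_index()
    return out


def _label(cohort: str, comparison: tuple[str, str], modality: str) -> str:
    return f"{modality}:{cohort}:{comparison[0]}-vs-{comparison[1]}"


def build_effect_matrix(
    splicing: list[ExonUsageResult] | None = None,
    expression: list[DGEResult] | None = None,
    gene_level: bool = False,
) -> EffectMatrix:
    """Assemble an EffectMatrix from per-analysis result tables.

    Splicing analyses contribute exon-level effects unless
    ``gene_level``, in which case they are first collapsed by
    :func:`aggregate_to_gene` (required when mixing with expression
    analyses, whose features are genes).
    """
    eff: dict[str, pd.Series] = {}
    z: dict[str, pd.Series] = {}
    sig: dict[str, pd.Series] = {}
    for r in splicing or []:
        lab = _label(r.cohort, r.comparison, "splicing")
        t = aggregate_to_gene(r) if gene_level else r.table[r.table["tested"].fillna(False)]
        eff[lab] = t["log2fc"]
        z[lab] = t["z"]
        sig[lab] = t["qvalue"] < 0.05
    for r in expression or []:
        lab = _label(r.cohort, r.comparison, "expression")
        eff[lab] = r.table["log2fc"]
        z[lab] = r.table["z"]
        sig[lab] = r.table["qvalue"] < 0.05
    if len(eff) < 1:
        raise ValueError("no analyses supplied")
    effects = pd.DataFrame(eff)
    flags = pd.DataFrame(sig).reindex(effects.index).fillna(False).astype(bool)
    zs = pd.DataFrame(z).reindex(effects.index)
    return EffectMatrix(effects=effects, significant=flags, zscores=zs)


def pairwise_sharing(
    m: EffectMatrix, pair: tuple[str, str], factor: float = SHARING_FACTOR
) -> tuple[float, int]:
    """Sharing fraction for one pair of analyses.

    Returns ``(fraction, n)`` where ``n`` is the number of features
    significant in at least one analysis with finite effects in both;
    ``fraction`` is NaN when ``n`` is zero.  An exact-zero effect shares
    sign with nothing.
    """
    a_lab, b_lab = pair
    for lab in pair:
        if lab not in m.effects.columns:
            raise KeyError(f"unknown analysis label {lab!r}")
    a = m.effects[a_lab].to_numpy(float)
    b = m.effects[b_lab].to_numpy(float)
    sig = m.significant[a_lab].to_numpy() | m.significant[b_lab].to_numpy()
    mask = sig & np.isfinite(a) & np.isfinite(b)
    n = int(mask.sum())
    if n == 0:
        return float("nan"), 0
    aa, bb = a[mask], b[mask]
    same_sign = aa * bb > 0
    lo = np.minimum(np.abs(aa), np.abs(bb))
    hi = np.maximum(np.abs(aa), np.abs(bb))
    shared = same_sign & (lo >= factor * hi)
    return float(shared.sum() / n), n


def sharing_matrix(m: EffectMatrix, factor: float = SHARING_FACTOR) -> SharingMatrix:
    """All-pairs sharing; symmetric by construction."""
    labs = m.analyses
    if len(labs) < 2:
        raise ValueError("need at least two analyses")
    frac = pd.DataFrame(np.nan, index=labs, columns=labs)
    nmat = pd.DataFrame(0, index=labs, columns=labs)
    for i, a in enumerate(labs):
        for b in labs[i:]:
            f, n = pairwise_sharing(m, (a, b), factor=factor)
            frac.loc[a, b] = frac.loc[b, a] = f
            nmat.loc[a, b] = nmat.loc[b, a] = n
    return SharingMatrix(fractions=frac, n_denominator=nmat)
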