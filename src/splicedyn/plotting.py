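"""Figure helpers: sharing heatmap, cluster trajectories, null histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, ClusterModel
from .gwas import EnrichmentResult
from .sharing import SharingMatrix


def plot_sharing_heatmap(sm: SharingMatrix, path: Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    data = sm.fractions.to_numpy(float)
    im = ax.imshow(data, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(sm.fractions)), sm.fractions.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(sm.fractions)), sm.fractions.index, fontsize=6)
    fig.colorbar(im, label="pairwise sharing")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cluster_trajectories(
    model: ClusterModel,
    assignment: ClusterAssignment,
    trajectories: pd.DataFrame,
    path: Path,
) -> None:
    k = model.k
    ncol = min(3, k)
    nrow = int(np.ceil(k / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    x = np.arange(trajectories.shape[1])
    for j in range(k):
        ax = axes[j // ncol][j % ncol]
        members = assignment.assignments.index[assignment.assignments == j]
        for eid in members[:200]:
            ax.plot(x, trajectories.loc[eid], color="grey", alpha=0.15, lw=0.6)
        ax.plot(x, model.centroids[j], color="black", lw=2)
        ax.set_title(
            f"cluster {j + 1} ({assignment.prevalence.loc[j]:.1f}%)", fontsize=8
        )
        ax.set_xticks(x, trajectories.columns, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_null_histogram(res: EnrichmentResult, path: Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(res.null_counts, bins=30, color="steelblue")
    ax.axvline(res.observed, color="black", linestyle="--",
               label=f"observed = {res.observed} ({res.call})")
    ax.set_xlabel("introns overlapping >=1 SNP")
    ax.set_ylabel("control sets")
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
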