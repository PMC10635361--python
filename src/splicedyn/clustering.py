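"""Fuzzy c-means clustering of exon-usage trajectories.

Exons called differentially used in either consecutive time-point
comparison of a cohort are clustered on their usage-coefficient
trajectories over the time course.  Trajectories are centered and scaled
(sample sd) so cluster shapes, not magnitudes, drive the grouping;
clustering uses fuzzy c-means with k = 6 and fuzzifier m = 2 by default,
and each exon is hard-assigned to its maximum-membership cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exon_usage import ExonUsageResult

logger = logging.getLogger(__name__)

#: canonical differentiation trajectory shapes on the usage-coefficient
#: scale (confluence, day 3, day 15): up-up, down-down, up-down, down-up,
#: up-flat, down-flat.  Amplitudes match strong usage shifts (|log2| ~ 2).
TEMPLATE_SHAPES = np.array(
    [
        [0.0, 1.0, 2.0],
        [0.0, -1.0, -2.0],
        [0.0, 2.0, -2.0],
        [0.0, -2.0, 2.0],
        [0.0, 2.0, 0.0],
        [0.0, -2.0, 0.0],
    ]
)


def template_trajectories(
    n_per_template: int = 100,
    sigma: float = 0.3,
    seed: int = 0,
    templates: np.ndarray = TEMPLATE_SHAPES,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Noisy trajectories drawn around the template shapes.

    Returns the raw (unstandardized) trajectories and the template label
    per row; used for clustering-recovery checks.
    """
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [t + rng.normal(0.0, sigma, (n_per_template, templates.shape[1]))
         for t in templates]
    )
    labels = np.repeat(np.arange(len(templates)), n_per_template)
    return pd.DataFrame(X), labels


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model on standardized trajectories."""

    centroids: np.ndarray          # (k, timepoints)
    membership: pd.DataFrame       # exons x k, rows sum to 1
    fuzzifier: float
    objective_trace: list[float] = field(default_factory=list)
    seed: int | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclass
class ClusterAssignment:
    """Hard assignments and per-cluster prevalence (percent of exons)."""

    assignments: pd.Series   # exon id -> cluster index (0-based)
    prevalence: pd.Series    # cluster index -> percent of all clustered exons


def select_cluster_input(results: list[ExonUsageResult], cohort: str) -> set[str]:
    """Union of q < 0.05 exons over the cohort's comparisons."""
    relevant = [r for r in results if r.cohort == cohort]
    if not relevant:
        raise ValueError(f"no results for cohort {cohort!r}")
    out: set[str] = set()
    for r in relevant:
        out |= set(r.significant_exons)
    return out


def center_scale(traj: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0 and sample sd 1 (ddof=1).

    Rows with zero variance carry no shape information and are dropped
    with a warning.
    """
    X = traj.to_numpy(float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d constant trajectories before clustering", n_drop)
    Z = (X[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(Z, index=traj.index[keep], columns=traj.columns)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [X[int(rng.integers(n))]]
    for _ in range(1, k):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            centers.append(X[int(rng.integers(n))])
            continue
        centers.append(X[int(rng.choice(n, p=d2 / total))])
    return np.asarray(centers)


def _cmeans_once(
    X: np.ndarray,
    k: int,
    m: float,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    C = _kmeanspp_init(X, k, rng)
    trace: list[float] = []
    U = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(-1)  # (n, k)
        U = _memberships(d2, m)
        obj = float((U**m * d2).sum())
        if trace and abs(trace[-1] - obj) < tol:
            trace.append(obj)
            break
        trace.append(obj)
        Um = U**m
        C = (Um.T @ X) / np.maximum(Um.sum(axis=0)[:, None], 1e-300)
    return C, U, trace


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """u_ij proportional to (1/d2_ij)^(1/(m-1)); exact hits get membership 1."""
    U = np.zeros_like(d2)
    zero = d2 <= 1e-300
    has_zero = zero.any(axis=1)
    if has_zero.any():
        rows = np.where(has_zero)[0]
        first = zero[rows].argmax(axis=1)
        U[rows, first] = 1.0
    rest = ~has_zero
    if rest.any():
        w = d2[rest] ** (-1.0 / (m - 1.0))
        U[rest] = w / w.sum(axis=1, keepdims=True)
    return U


def fuzzy_cmeans(
    X: pd.DataFrame | np.ndarray,
    k: int = 6,
    m: float = 2.0,
    tol: float = 1e-9,
    max_iter: int = 1000,
    seed: int = 0,
    n_restarts: int = 5,
) -> ClusterModel:
    """Fuzzy c-means with k-means++ seeding and restarts.

    Alternates the standard membership and centroid updates until the
    objective sum(u^m * d^2) changes by less than ``tol``; the best of
    ``n_restarts`` differently-seeded runs is returned.
    """
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    Xa = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if m <= 1.0:
        raise ValueError("fuzzifier m must be > 1")
    if len(np.unique(Xa, axis=0)) < k:
        raise ValueError(f"need at least k={k} distinct points")
    root = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_restarts):
        C, U, trace = _cmeans_once(Xa, k, m, tol, max_iter, root)
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], C, U, trace)
    assert best is not None
    _, C, U, trace = best
    cols = pd.RangeIndex(k, name="cluster")
    return ClusterModel(
        centroids=C,
        membership=pd.DataFrame(U, index=index, columns=cols),
        fuzzifier=m,
        objective_trace=trace,
        seed=seed,
    )


def assign_and_prevalence(model: ClusterModel) -> ClusterAssignment:
    """Max-membership hard assignment; ties go to the lowest cluster index."""
    U = model.membership.to_numpy()
    hard = U.argmax(axis=1)  # argmax takes the first maximum: lowest index
    assignments = pd.Series(hard, index=model.membership.index, name="cluster")
    sizes = assignments.value_counts().reindex(range(model.k), fill_value=0)
    prevalence = 100.0 * sizes / len(assignments)
    prevalence.index.name = "cluster"
    return ClusterAssignment(assignments=assignments, prevalence=prevalence)


def match_clusters_across_cohorts(
    models: dict[str, ClusterModel],
    reference: str | None = None,
    max_distance: float = 1.0,
) -> pd.DataFrame:
    """Greedily match centroids of each cohort to a reference cohort's.

    Pairs are taken in order of increasing Euclidean centroid distance;
    centroids whose best remaining partner lies beyond ``max_distance``
    are reported unmatched (cohort-specific shape).  Returns a tidy
    DataFrame (cohort, cluster, reference_cluster or -1, distance).
    """
    if not models:
        raise ValueError("no models supplied")
    names = list(models)
    reference = reference or names[0]
    ref = models[reference].centroids
    rows = []
    for name in names:
        if name == reference:
            for j in range(models[name].k):
                rows.append((name, j, j, 0.0))
            continue
        C = models[name].centroids
        d = np.sqrt(((C[:, None, :] - ref[None, :, :]) ** 2).sum(-1))
        free_a = set(range(C.shape[0]))
        free_b = set(range(ref.shape[0]))
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for i, j in order:
            if i in free_a and j in free_b and d[i, j] <= max_distance:
                rows.append((name, int(i), int(j), float(d[i, j])))
                free_a.discard(int(i))
                free_b.discard(int(j))
        for i in sorted(free_a):
            rows.append((name, int(i), -1, float("nan")))
    return pd.DataFrame(
        rows, columns=["cohort", "cluster", "reference_cluster", "distance"]
    )
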