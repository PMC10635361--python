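"""Count-model numerics: BH correction, NB dispersion, batched NB GLM.

The differential-usage and differential-expression tests fit many small
negative-binomial GLMs that all share a single design matrix (one fit per
exon or per gene, identical covariates).  The IRLS solver below is
therefore vectorized across units: parameters are updated for all units
simultaneously with batched weighted least squares, which is orders of
magnitude faster than looping over per-unit model objects while giving
the same estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2, norm

_ETA_MAX = 30.0  # linear-predictor clamp; exp(30) >> any realistic count


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    Parameters
    ----------
    pvalues
        Array of p-values in [0, 1].  NaNs are propagated (excluded from
        the correction and returned as NaN).
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if ((pm < 0) | (pm > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = pm.size
    if n == 0:
        return out
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qvals = np.empty(n)
    qvals[order] = q
    out[mask] = qvals
    return out


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log-likelihood.

    ``y``/``mu`` are (units, obs); ``alpha`` is (units,) or (units, obs)
    — per-observation dispersion supports models whose observations are
    aggregates with differing dispersion (e.g. an exon vs the sum of its
    gene's other exons).
    """
    mu = np.maximum(mu, 1e-10)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    r = 1.0 / np.maximum(alpha, 1e-12)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


@dataclass
class NBGLMFit:
    """Result of a batched NB GLM fit (one row per unit)."""

    beta: np.ndarray        # (units, p)
    se: np.ndarray          # (units, p) Wald standard errors
    loglik: np.ndarray      # (units,)
    mu: np.ndarray          # (units, obs) fitted means
    converged: np.ndarray   # (units,) bool
    n_iter: int


def fit_nb_glm(
    Y: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray,
    offset: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NBGLMFit:
    """Fit ``units`` independent NB GLMs with log link and shared design.

    Parameters
    ----------
    Y
        Counts, shape (units, obs).
    X
        Design matrix, shape (obs, p); column 0 must be the intercept.
    alpha
        NB2 dispersion per unit (Var = mu + alpha * mu^2).
    offset
        Log-scale offset, shape (obs,) or (units, obs).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n_units, n_obs = Y.shape
    p = X.shape[1]
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim <= 1:
        alpha = np.broadcast_to(alpha, (n_units,))[:, None]
    alpha = np.broadcast_to(alpha, (n_units, n_obs))
    if offset is None:
        off = np.zeros((1, n_obs))
    else:
        off = np.atleast_2d(np.asarray(offset, dtype=float))

    beta = np.zeros((n_units, p))
    base = np.log(np.maximum(Y / np.exp(off), 1e-8).mean(axis=1))
    beta[:, 0] = base

    ll_old = np.full(n_units, -np.inf)
    converged = np.zeros(n_units, dtype=bool)
    XtWX = np.empty((n_units, p, p))
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(beta @ X.T + off, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - off) + (Y - mu) / mu
        XtWX = np.einsum("ui,ij,ik->ujk", W, X, X, optimize=True)
        XtWX[:, np.arange(p), np.arange(p)] += 1e-10
        XtWz = np.einsum("ui,ij->uj", W * z, X, optimize=True)
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        # step-halving where the likelihood would decrease
        ll_new = nb_loglik(Y, np.exp(np.clip(beta_new @ X.T + off, -_ETA_MAX, _ETA_MAX)), alpha)
        worse = ll_new < ll_old - 1e-10
        if worse.any():
            half = 0.5 * (beta_new[worse] + beta[worse])
            beta_new[worse] = half
            ll_new[worse] = nb_loglik(
                Y[worse],
                np.exp(np.clip(half @ X.T + (off if off.shape[0] == 1 else off[worse]), -_ETA_MAX, _ETA_MAX)),
                alpha[worse],
            )
        delta = np.abs(ll_new - ll_old)
        beta = beta_new
        ll_old = ll_new
        converged = delta < tol
        if converged.all():
            break

    eta = np.clip(beta @ X.T + off, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    XtWX = np.einsum("ui,ij,ik->ujk", W, X, X, optimize=True)
    XtWX[:, np.arange(p), np.arange(p)] += 1e-10
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return NBGLMFit(beta=beta, se=se, loglik=ll_old, mu=mu, converged=converged, n_iter=it)


def lrt_pvalues(ll_full: np.ndarray, ll_reduced: np.ndarray, df: int = 1) -> np.ndarray:
    """Likelihood-ratio test p-values; negative statistics are clipped to 0."""
    stat = np.maximum(2.0 * (ll_full - ll_reduced), 0.0)
    return chi2.sf(stat, df)


def wald_pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    return 2.0 * norm.sf(np.abs(z))


def estimate_dispersion(
    Y_norm: np.ndarray,
    groups: np.ndarray,
    floor: float = 1e-4,
    trend_weight: float = 0.5,
    n_bins: int = 10,
) -> np.ndarray:
    """Method-of-moments NB dispersion with trend shrinkage.

    Per unit, a pooled MoM estimate of alpha is computed from the
    within-group means and variances of normalized counts; estimates are
    then shrunk ``trend_weight``/(1-``trend_weight``) toward the median
    dispersion of units with similar mean counts, and floored.  Designed
    for n=3-per-group layouts where raw MoM is unusably noisy.
    """
    Y_norm = np.asarray(Y_norm, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    num = np.zeros(Y_norm.shape[0])
    den = np.zeros(Y_norm.shape[0])
    for g in labels:
        sub = Y_norm[:, groups == g]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = sub.shape[1] - 1
        num += w * (v - m)
        den += w * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, floor)
    raw = np.clip(raw, floor, 10.0)

    mean_all = Y_norm.mean(axis=1)
    order = np.argsort(mean_all, kind="stable")
    trend = np.full_like(raw, np.median(raw))
    n = raw.size
    if n >= n_bins * 2:
        edges = np.array_split(order, n_bins)
        for idx in edges:
            trend[idx] = np.median(raw[idx])
    shrunk = (1.0 - trend_weight) * raw + trend_weight * trend
    return np.maximum(shrunk, floor)


def size_factors_median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors over rows (features) of a counts matrix.

    Uses the median ratio to the geometric-mean pseudo-reference over
    features that are nonzero in every sample; falls back to total-count
    scaling if fewer than 10 such features exist.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.sum() >= 10:
        logc = np.log(counts[positive])
        ref = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - ref, axis=0))
    else:
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))
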