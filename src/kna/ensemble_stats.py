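"""Ensemble comparison of compositional frequency tables.

An image ensemble is a matrix of per-image group (or bin) frequencies —
compositional data, each row summing to one.  Analysis follows the
standard log-ratio route: centred log-ratio (CLR) transform, column
centring, PCA, and between-component analysis (BCA: PCA of the condition
means with all images projected onto that space) to visualise condition
separation.  Differences between conditions are tested by permutation:
a homogeneity-of-multivariate-dispersions test (distances to condition
centroids, one-way F statistic, label permutation) and a multivariate
mean-difference test (size-weighted sum of squared centroid-to-grand-mean
distances, label permutation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OrdinationResult",
    "PermutationTestResult",
    "logratio_transform",
    "ordinate",
    "correspondence_analysis",
    "dispersion_test",
    "mean_difference_test",
]


def logratio_transform(
    freq, pseudocount: float = 0.5, policy: str = "pseudocount"
) -> np.ndarray:
    """Centred log-ratio transform of a compositional matrix.

    ``freq`` is an (images x parts) matrix of counts or frequencies.
    Zeros are handled by ``policy``: ``"pseudocount"`` adds ``pseudocount``
    to every entry of the matrix before closure whenever any entry is
    zero; ``"strict"`` raises, naming the offending cells.  Rows are then
    closed (renormalised), logged and row-centred, making the result
    invariant to row scaling; finally columns are mean-centred for PCA.
    """
    x = np.asarray(freq, dtype=float)
    if isinstance(freq, pd.DataFrame):
        x = freq.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("frequencies must be non-negative")
    if np.any(x == 0):
        if policy == "strict":
            rows, cols = np.nonzero(x == 0)
            raise ValueError(
                f"zero entries at (row, col): {list(zip(rows.tolist(), cols.tolist()))[:10]}"
            )
        x = x + pseudocount
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return clr - clr.mean(axis=0, keepdims=True)


@dataclass(frozen=True)
class OrdinationResult:
    """Scores and loadings of the log-ratio PCA and its BCA refinement."""

    scores: np.ndarray           # images x components, PCA of CLR matrix
    loadings: np.ndarray         # components x parts
    variance_explained: np.ndarray
    bca_scores: np.ndarray       # images x (n_conditions - 1 at most)
    bca_loadings: np.ndarray
    bca_variance: np.ndarray     # between-condition variance per BCA axis
    conditions: np.ndarray
    between_variance_fraction: float


def _pca(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    _, svals, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    var = svals**2 / max(len(x) - 1, 1)
    return x @ vt.T, vt, var


def ordinate(transformed: np.ndarray, conditions) -> OrdinationResult:
    """PCA of the (already column-centred) CLR matrix, then BCA.

    BCA is the PCA of the condition-mean rows, weighted by condition
    size, with every image projected onto the resulting axes — the
    ordination that maximises between-condition separation.  Requires at
    least two conditions with at least two images each.
    """
    x = np.asarray(transformed, float)
    conditions = np.asarray(conditions)
    levels, inverse, counts = np.unique(
        conditions, return_inverse=True, return_counts=True
    )
    if len(levels) < 2:
        raise ValueError("need at least two conditions")
    if counts.min() < 2:
        bad = levels[counts < 2]
        raise ValueError(f"conditions with a single image: {bad.tolist()}")

    x = x - x.mean(axis=0)
    scores, loadings, var = _pca(x)

    means = np.vstack([x[inverse == g].mean(axis=0) for g in range(len(levels))])
    weights = counts / counts.sum()
    # weighted PCA of the class means about the (zero) grand mean
    cov = (means * weights[:, None]).T @ means
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][: len(levels) - 1]
    bca_axes = evecs[:, order].T
    bca_var = evals[order]
    # deterministic sign: largest-magnitude entry positive
    for row in bca_axes:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    bca_scores = x @ bca_axes.T
    total_var = (x**2).sum() / len(x)
    between = float(bca_var.sum() / total_var) if total_var > 0 else 0.0
    return OrdinationResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var / var.sum() if var.sum() else var,
        bca_scores=bca_scores,
        bca_loadings=bca_axes,
        bca_variance=bca_var,
        conditions=conditions,
        between_variance_fraction=between,
    )


def correspondence_analysis(
    freq, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correspondence analysis of a frequency matrix (alternative view).

    Chi-square-metric SVD of the standardised residuals of an
    images x parts count/frequency matrix.  Returns ``(row_scores,
    column_scores, inertia_share)`` with principal-coordinate rows.
    Offered as an alternative to the log-ratio route for readers used to
    CA ordinations; the log-ratio PCA remains the primary analysis.
    """
    x = np.asarray(freq, float)
    if isinstance(freq, pd.DataFrame):
        x = freq.to_numpy(dtype=float)
    if np.any(x < 0) or x.sum() == 0:
        raise ValueError("frequencies must be non-negative and not all zero")
    p = x / x.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValueError("empty rows/columns are not allowed")
    resid = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, svals, vt = np.linalg.svd(resid, full_matrices=False)
    keep = slice(0, n_components)
    row_scores = (u[:, keep] * svals[keep]) / np.sqrt(r)[:, None]
    col_scores = (vt[keep].T * svals[keep]) / np.sqrt(c)[:, None]
    inertia = svals**2
    share = inertia[keep] / inertia.sum() if inertia.sum() else inertia[keep]
    return row_scores, col_scores, share


@dataclass(frozen=True)
class PermutationTestResult:
    """Outcome of a label-permutation test.

    ``p_value`` uses the add-one rule
    ``(1 + #{null >= observed}) / (1 + n_perm)``, so it is never zero.
    """

    statistic: float
    p_value: float
    n_perm: int
    seed: int
    null_distribution: np.ndarray | None = None


def _check_perm_args(conditions: np.ndarray, n_perm: int) -> np.ndarray:
    levels = np.unique(conditions)
    if len(levels) < 2:
        raise ValueError("need at least two conditions")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse", stacklevel=3)
    return levels


def _anova_f(values: np.ndarray, inverse: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F statistic on scalar values."""
    n = len(values)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        v = values[inverse == g]
        m = v.mean()
        ss_between += len(v) * (m - grand) ** 2
        ss_within += ((v - m) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def dispersion_test(
    scores: np.ndarray,
    conditions,
    n_perm: int = 9999,
    seed: int = 0,
    keep_null: bool = False,
) -> PermutationTestResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Each image's Euclidean distance to its condition centroid (the
    multivariate mean) is computed; the observed statistic is the one-way
    ANOVA F over those distances, and the null is built by permuting the
    distances across condition labels.  A large statistic means the
    conditions differ in spread (image-to-image variability) rather than
    in location.
    """
    x = np.atleast_2d(np.asarray(scores, float))
    if x.shape[0] == 1:
        x = x.T
    conditions = np.asarray(conditions)
    _check_perm_args(conditions, n_perm)
    levels, inverse = np.unique(conditions, return_inverse=True)
    dists = np.empty(len(x))
    for g in range(len(levels)):
        mask = inverse == g
        centroid = x[mask].mean(axis=0)
        dists[mask] = np.linalg.norm(x[mask] - centroid, axis=1)
    observed = _anova_f(dists, inverse, len(levels))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _anova_f(dists, rng.permutation(inverse), len(levels))
    p = (1 + np.sum(null >= observed)) / (1 + n_perm)
    return PermutationTestResult(
        float(observed), float(p), n_perm, seed, null if keep_null else None
    )


def _between_ss(x: np.ndarray, inverse: np.ndarray, n_groups: int) -> float:
    grand = x.mean(axis=0)
    ss = 0.0
    for g in range(n_groups):
        xg = x[inverse == g]
        ss += len(xg) * float(((xg.mean(axis=0) - grand) ** 2).sum())
    return ss


def mean_difference_test(
    scores: np.ndarray,
    conditions,
    n_perm: int = 9999,
    seed: int = 0,
    keep_null: bool = False,
) -> PermutationTestResult:
    """Permutation test for differences in multivariate means.

    The statistic is the size-weighted between-condition sum of squares:
    ``sum_g n_g * ||mean_g - grand_mean||**2``; the null is built by
    permuting condition labels over images.
    """
    x = np.atleast_2d(np.asarray(scores, float))
    if x.shape[0] == 1:
        x = x.T
    conditions = np.asarray(conditions)
    _check_perm_args(conditions, n_perm)
    levels, inverse = np.unique(conditions, return_inverse=True)
    observed = _between_ss(x, inverse, len(levels))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _between_ss(x, rng.permutation(inverse), len(levels))
    p = (1 + np.sum(null >= observed)) / (1 + n_perm)
    return PermutationTestResult(
        float(observed), float(p), n_perm, seed, null if keep_null else None
    )
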