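"""Linear decomposition of brain-map ensembles.

PCA over an M x N matrix of maps (subjects x parcels) identifies dominant
spatial modes of variation; per-component significance is assessed by a
permutation null in which every map's parcels are shuffled independently.
A subspace projection quantifies how much of one ensemble's variance falls
within another's leading components, and per-parcel regressions of
behavioral score changes on change-in-GBC yield "experiential regression
maps" of slopes across the cortex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PCAResult",
    "RegressionMaps",
    "pca",
    "pc_permutation_test",
    "subspace_variance_fraction",
    "experiential_regression_maps",
]

DEFAULT_SCALE_NAMES = [
    "disembodiment",
    "elementary_imagery",
    "changed_meaning_of_percepts",
    "blissful_state",
    "spiritual_experience",
]


@dataclass
class PCAResult:
    """Eigendecomposition of the spatial covariance of a map ensemble.

    Columns of P are principal components ordered by descending
    eigenvalue; sign convention: each component's largest-magnitude
    element is positive.
    """

    P: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    column_means: np.ndarray


def pca(X: np.ndarray) -> PCAResult:
    """PCA of M maps over N parcels via C = X^T X / (M-1), columns centered."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be M x N with M >= 2 maps")
    mu = X.mean(axis=0)
    Xc = X - mu
    C = Xc.T @ Xc / (X.shape[0] - 1)
    lam, P = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    P = P[:, order]
    # deterministic sign: largest-magnitude element of each PC is positive
    for j in range(P.shape[1]):
        k = np.argmax(np.abs(P[:, j]))
        if P[k, j] < 0:
            P[:, j] = -P[:, j]
    tr = lam.sum()
    frac = lam / tr if tr > 0 else np.zeros_like(lam)
    return PCAResult(P=P, eigenvalues=lam, variance_fractions=frac, column_means=mu)


def pc_permutation_test(
    X: np.ndarray, n_perm: int, seed: int, alpha: float = 0.05
) -> dict:
    """Permutation null for per-PC variance fractions.

    Each permutation shuffles every row (map) independently across
    parcels, destroying spatial structure while preserving each map's
    value distribution. A component is flagged significant when its
    observed variance fraction exceeds the null's upper (1 - alpha)
    percentile; both the 5th and 95th null percentiles are returned.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; null percentiles are coarse", stacklevel=2)
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    observed = pca(X).variance_fractions
    null = np.empty((n_perm, observed.size))
    for t in range(n_perm):
        Xp = np.array([row[rng.permutation(row.size)] for row in X])
        null[t] = pca(Xp).variance_fractions
    p95 = np.percentile(null, 100 * (1 - alpha), axis=0)
    p5 = np.percentile(null, 100 * alpha, axis=0)
    return {
        "observed": observed,
        "null": null,
        "null_p95": p95,
        "null_p5": p5,
        "significant": (observed > p95) & (observed > 1e-12),
    }


def subspace_variance_fraction(C_model: np.ndarray, P_emp: np.ndarray) -> float:
    """Fraction of covariance trace captured inside an orthonormal basis.

    trace(P^T C P) / trace(C) for an N x k basis with orthonormal columns.
    """
    C = np.asarray(C_model, dtype=float)
    P = np.asarray(P_emp, dtype=float)
    if P.ndim != 2 or P.shape[0] != C.shape[0]:
        raise ValueError("basis must be N x k matching C")
    if not np.allclose(P.T @ P, np.eye(P.shape[1]), atol=1e-8):
        raise ValueError("basis columns must be orthonormal")
    return float(np.trace(P.T @ C @ P) / np.trace(C))


@dataclass
class RegressionMaps:
    """Per-parcel OLS slope and intercept maps of score change on map change."""

    beta: np.ndarray  # N x n_scales
    alpha: np.ndarray  # N x n_scales
    scale_names: list[str]


def experiential_regression_maps(
    dgbc: np.ndarray,
    scores: np.ndarray,
    scale_names: list[str] | None = None,
) -> RegressionMaps:
    """Regress each score dimension on each parcel's change across subjects.

    For parcel i and score dimension d, fits score_d = alpha + beta *
    dgbc_i by ordinary least squares over the M subjects. A zero-variance
    parcel yields NaN coefficients with a warning.
    """
    dgbc = np.asarray(dgbc, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if dgbc.ndim != 2 or scores.ndim != 2 or dgbc.shape[0] != scores.shape[0]:
        raise ValueError("dgbc (M x N) and scores (M x d) must share the subject axis")
    M, N = dgbc.shape
    if M < 3:
        raise ValueError("need at least 3 subjects")
    d = scores.shape[1]
    if scale_names is None:
        scale_names = DEFAULT_SCALE_NAMES[:d] if d <= 5 else [f"scale{j}" for j in range(d)]
    Xc = dgbc - dgbc.mean(axis=0)
    Yc = scores - scores.mean(axis=0)
    var = (Xc**2).sum(axis=0)
    beta = np.full((N, d), np.nan)
    good = var > 0
    if not np.all(good):
        warnings.warn("zero-variance parcels; slopes set to NaN", stacklevel=2)
    beta[good] = (Xc[:, good].T @ Yc) / var[good, None]
    alpha = scores.mean(axis=0)[None, :] - beta * dgbc.mean(axis=0)[:, None]
    return RegressionMaps(beta=beta, alpha=alpha, scale_names=list(scale_names))
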