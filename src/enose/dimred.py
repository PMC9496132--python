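"""PCA, factor analysis, and LDA with a shared fit/transform contract.

All three methods produce a :class:`ProjectionModel` holding the fitted
mean, unit-norm component directions (columns of a d x k matrix) and a
per-component score: the explained-variance ratio for PCA, the Fisher
generalized eigenvalue for LDA, and the share of common variance for FA.
The sign of each component is fixed so its largest-magnitude entry is
positive, making fits deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "ProjectionModel",
    "fit_pca",
    "fit_lda",
    "fit_fa",
    "transform",
    "inverse_transform",
]


@dataclass
class ProjectionModel:
    method: str  # "PCA" | "FA" | "LDA"
    mean: np.ndarray
    components: np.ndarray  # d x k, unit-norm columns
    k: int
    explained: np.ndarray
    #: per-feature scale applied before projection (ones except for FA,
    #: which operates on the correlation matrix, i.e. standardized data)
    scale: np.ndarray | None = None
    #: raw FA loadings (columns scaled by sqrt eigenvalue); None otherwise
    loadings: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != (len(self.mean), self.k):
            raise ValueError("components must be d x k")

    @property
    def d(self) -> int:
        return len(self.mean)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    out = components.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _unit_columns(components: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(components, axis=0)
    norms[norms == 0] = 1.0
    return components / norms


def fit_pca(X: np.ndarray, k: int) -> ProjectionModel:
    """Top-k eigenvectors of the covariance of centered X, in descending
    eigenvalue order. `explained` holds the variance ratios."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 1 <= k <= min(n - 1, d):
        raise ValueError(f"k must be in [1, {min(n - 1, d)}], got {k}")
    mu = X.mean(axis=0)
    S = np.cov(X - mu, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    ratios = evals[:k] / total if total > 0 else np.zeros(k)
    comps = _fix_signs(_unit_columns(evecs[:, :k]))
    return ProjectionModel("PCA", mu, comps, k, ratios)


def fit_lda(
    X: np.ndarray, labels: np.ndarray, k: int, ridge_rel: float = 1e-6
) -> ProjectionModel:
    """Fisher discriminant directions: solve S_B w = lambda S_W w.

    At most ``n_classes - 1`` informative directions exist. The within-class
    scatter is ridge-regularized (relative to its trace) when
    ill-conditioned, as feature counts can approach per-class sample counts.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    n_classes = len(classes)
    if k > n_classes - 1:
        raise ValueError(
            f"LDA supports at most n_classes - 1 = {n_classes - 1} "
            f"components, got k={k}"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    d = X.shape[1]
    mu = X.mean(axis=0)
    S_W = np.zeros((d, d))
    S_B = np.zeros((d, d))
    for lab in classes:
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            raise ValueError(f"class {lab!r} needs at least 2 samples")
        Xc = X[idx]
        mc = Xc.mean(axis=0)
        dev = Xc - mc
        S_W += dev.T @ dev
        diff = (mc - mu)[:, None]
        S_B += len(idx) * (diff @ diff.T)
    cond = np.linalg.cond(S_W)
    if not np.isfinite(cond) or cond > 1e10:
        lam = ridge_rel * np.trace(S_W) / d
        if lam <= 0:  # degenerate: zero within-class scatter
            lam = ridge_rel
        S_W = S_W + lam * np.eye(d)
    evals, evecs = linalg.eigh(S_B, S_W)
    order = np.argsort(evals)[::-1]
    evals = evals[order][:k]
    comps = _fix_signs(_unit_columns(evecs[:, order][:, :k]))
    return ProjectionModel("LDA", mu, comps, k, np.maximum(evals, 0.0))


def fit_fa(
    X: np.ndarray, k: int, max_iter: int = 500, tol: float = 1e-3
) -> ProjectionModel:
    """k-factor model by iterated principal-factor extraction.

    Operates on the correlation matrix: communalities on the diagonal are
    re-estimated from the current loadings until convergence. `explained`
    is each factor's share of total (unit) variance. Deterministic: no
    random initialization is involved.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}]")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    R = np.corrcoef((X - mu) / sd, rowvar=False)
    R = np.atleast_2d(np.nan_to_num(R, nan=0.0))
    np.fill_diagonal(R, 1.0)
    # initial communalities: squared multiple correlations where invertible
    try:
        Rinv = np.linalg.inv(R + 1e-8 * np.eye(d))
        h2 = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        h2 = np.abs(R - np.eye(d)).max(axis=0)
    h2 = np.clip(h2, 0.0, 1.0)
    loadings = None
    for it in range(max_iter):
        Rstar = R.copy()
        np.fill_diagonal(Rstar, h2)
        evals, evecs = np.linalg.eigh(Rstar)
        order = np.argsort(evals)[::-1][:k]
        lam = np.maximum(evals[order], 0.0)
        loadings = evecs[:, order] * np.sqrt(lam)
        h2_new = np.clip((loadings**2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    else:
        raise RuntimeError(
            f"principal-factor iteration did not converge in {max_iter} "
            "iterations"
        )
    # Heywood guard: rescale any variable whose communality drifted above 1
    h2_final = (loadings**2).sum(axis=1)
    over = h2_final > 1.0
    if over.any():
        loadings[over] /= np.sqrt(h2_final[over])[:, None]
    loadings = _fix_signs(loadings)
    comps = _fix_signs(_unit_columns(loadings))
    explained = (loadings**2).sum(axis=0) / d
    return ProjectionModel("FA", mu, comps, k, explained, scale=sd, loadings=loadings)


def transform(model: ProjectionModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X: ``(X - mean) [/ scale] @ components``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.d:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.d}"
        )
    Z = X - model.mean
    if model.scale is not None:
        Z = Z / model.scale
    return Z @ model.components


def inverse_transform(model: ProjectionModel, Y: np.ndarray) -> np.ndarray:
    """Map k-dimensional scores back to the original space (exact only for
    orthonormal components, i.e. PCA)."""
    Y = np.asarray(Y, dtype=float)
    Z = Y @ model.components.T
    if model.scale is not None:
        Z = Z * model.scale
    return Z + model.mean
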