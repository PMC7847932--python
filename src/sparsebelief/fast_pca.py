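"""Exact PCA with the snapshot (Gram-matrix) fast path.

Voxel-level neuroimaging matrices are extremely wide: a few hundred
subjects by ~10^5 voxels.  Direct eigendecomposition of the p × p feature
covariance is infeasible, but the n × n Gram matrix of the centered data
has the same nonzero spectrum, and its eigenvectors map back to the
feature-space principal axes.  This "snapshot" path is exact PCA, not an
approximation; a thin SVD is used when n >= p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._utils import ValidationError, as_2d_float

__all__ = ["PCAModel", "fit_fast_pca", "transform", "inverse_transform", "select_k_for_variance"]

_EIG_FLOOR = 1e-12  # relative eigenvalue cutoff for numerically null directions


@dataclass
class PCAModel:
    """Fitted principal-component basis.

    components has orthonormal rows (k × p); explained_variance are the
    per-component score variances (descending, denominator n − 1);
    explained_variance_ratio divides by the total data variance.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    if components.size == 0:
        return components
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


def fit_fast_pca(X: np.ndarray, k: int) -> PCAModel:
    """Top-k principal axes of the column-centered data.

    When p > n the axes are recovered from the eigendecomposition of the
    n × n Gram matrix Xc Xcᵀ; otherwise from a thin SVD of Xc.  Both paths
    give identical results up to sign (enforced deterministic).
    """
    X = as_2d_float(X, "X")
    n, p = X.shape
    if n < 2:
        raise ValidationError(f"need at least 2 samples, got {n}")
    if not (1 <= k <= min(n, p)):
        raise ValidationError(f"k={k} out of range [1, {min(n, p)}]")

    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc ** 2).sum()) / (n - 1)
    if total_var <= 0.0:
        warnings.warn("zero-variance data: PCA model has no components")
        return PCAModel(mean, np.empty((0, p)), np.empty(0), np.empty(0))

    if p > n:
        # snapshot path: Xc Xcᵀ u = s² u ; v = Xcᵀ u / s
        G = Xc @ Xc.T
        eigval, eigvec = np.linalg.eigh(G)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        keep = eigval > _EIG_FLOOR * eigval[0]
        eigval, eigvec = eigval[keep], eigvec[:, keep]
        s = np.sqrt(eigval)
        V = (Xc.T @ eigvec) / s  # (p, r) orthonormal columns
        components = V.T
        variances = eigval / (n - 1)
    else:
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        keep = s > np.sqrt(_EIG_FLOOR) * s[0]
        s, Vt = s[keep], Vt[keep]
        components = Vt
        variances = s ** 2 / (n - 1)

    r = components.shape[0]
    if k > r:
        warnings.warn(
            f"requested k={k} exceeds numerical rank {r}; returning {r} components"
        )
        k = r
    components = _fix_signs(components[:k])
    variances = variances[:k]
    return PCAModel(mean, components, variances, variances / total_var)


def transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X onto the fitted component basis."""
    X = as_2d_float(X, "X")
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"X has {X.shape[1]} features, model expects {model.n_features}"
        )
    return (X - model.mean) @ model.components.T


def inverse_transform(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map component scores back to (approximate) feature space."""
    scores = as_2d_float(scores, "scores")
    if scores.shape[1] != model.n_components:
        raise ValidationError(
            f"scores have {scores.shape[1]} columns, model has {model.n_components} components"
        )
    return scores @ model.components + model.mean


def select_k_for_variance(ratios, threshold: float = 0.90) -> int:
    """Smallest k whose cumulative explained-variance ratio reaches threshold.

    With the default 0.90 threshold this is the rule that, on the original
    amyloid-PET/MRI study data, retained the top 20 components carrying 90%
    of the information.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    if ratios.size == 0:
        raise ValidationError("ratios must be nonempty")
    if np.any(ratios < 0):
        raise ValidationError("ratios must be nonnegative")
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    cum = np.cumsum(ratios)
    hit = np.nonzero(cum >= threshold - 1e-12)[0]
    if hit.size == 0:
        warnings.warn(
            f"total explained variance {cum[-1]:.4f} below threshold {threshold}; "
            "returning all components"
        )
        return int(ratios.size)
    return int(hit[0] + 1)
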