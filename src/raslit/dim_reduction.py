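"""Principal component analysis: standardize, covariance, eigendecomposition.

The procedure is the textbook route: standardize the data matrix X (samples ×
features) into Z, take the sample covariance Σ = ZᵀZ/(n−1), solve Σv = λv,
sort eigenvalues descending, keep the top k eigenvectors V_k and project
T = Z V_k.

Because the intended regime has far more features (documents) than samples
(genes), the decomposition is computed through the thin SVD of Z: with
Z = U S Vᵀ, the eigenvalues of Σ are λ_i = s_i²/(n−1) and its eigenvectors are
the right singular vectors — identical to the d × d eigendecomposition for the
top min(n−1, d) components, but without ever forming the d × d matrix.

Sign convention: each component is flipped so that its largest-magnitude
loading is positive, making the decomposition deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center columns and scale to unit sample standard deviation (ddof=1).

    Constant columns are centered and left at zero (their std divisor is
    replaced by 1). Returns (Z, means, stds) with the *replaced* stds.
    Requires at least two samples.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples × features)")
    if X.shape[0] < 2:
        raise ValueError("standardization requires at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1)
    constant = stds <= 1e-15 * np.maximum(1.0, np.abs(means))
    safe = np.where(constant, 1.0, stds)
    Z = (X - means) / safe
    Z[:, constant] = 0.0
    return Z, means, safe


class StandardizedPCA(BaseEstimator, TransformerMixin):
    """PCA on internally standardized data.

    Parameters
    ----------
    n_components : int, optional
        Number of components to keep. Clipped (with a warning) to the rank of
        the standardized matrix.
    variance_target : float in (0, 1], optional
        Alternative to ``n_components``: keep the smallest k whose cumulative
        explained-variance fraction reaches the target. Default 0.95 when
        neither is given.

    Attributes
    ----------
    means_, stds_ : per-feature standardization parameters (ddof=1).
    constant_mask_ : boolean mask of constant input features (kept at zero).
    components_ : (d, k) matrix V_k, orthonormal columns.
    eigenvalues_ : k descending eigenvalues of the sample covariance.
    explained_variance_ratio_ : eigenvalues over the covariance trace.
    n_components_ : retained dimension k.
    """

    def __init__(self, n_components: int | None = None,
                 variance_target: float | None = None):
        self.n_components = n_components
        self.variance_target = variance_target

    def _standardize_new(self, X) -> np.ndarray:
        X = np.asarray(X.toarray() if sp.issparse(X) else X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.means_.shape[0]:
            raise ValueError(
                f"feature count mismatch: got {X.shape[1]}, model has "
                f"{self.means_.shape[0]}")
        Z = (X - self.means_) / self.stds_
        Z[:, self.constant_mask_] = 0.0
        return Z

    def fit(self, X, y=None):
        if self.n_components is not None and self.variance_target is not None:
            raise ValueError("give n_components or variance_target, not both")
        X = np.asarray(X.toarray() if sp.issparse(X) else X, dtype=float)
        Z, self.means_, self.stds_ = standardize(X)
        self.constant_mask_ = np.abs(Z).max(axis=0) == 0.0
        n = Z.shape[0]

        # Thin SVD route; eigenvalues of Σ = ZᵀZ/(n−1) are s²/(n−1).
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        eigenvalues = s ** 2 / (n - 1)
        rank = int(np.sum(s > s[0] * max(Z.shape) * np.finfo(float).eps)) if s.size else 0
        total_variance = float(np.sum(~self.constant_mask_))  # trace of Σ

        if self.variance_target is not None:
            if not 0 < self.variance_target <= 1:
                raise ValueError("variance_target must be in (0, 1]")
            frac = np.cumsum(eigenvalues) / total_variance if total_variance else np.array([])
            k = int(np.searchsorted(frac, self.variance_target) + 1)
            k = min(k, rank) if rank else 0
        else:
            k = self.n_components if self.n_components is not None else None
            if k is None:
                frac = np.cumsum(eigenvalues) / total_variance if total_variance else np.array([])
                k = int(np.searchsorted(frac, 0.95) + 1)
                k = min(k, rank) if rank else 0
            elif k > rank:
                logger.warning("requested k=%d exceeds rank %d; clipping", k, rank)
                k = rank

        components = Vt[:k].T  # d × k
        # Deterministic sign: largest-magnitude loading of each component > 0.
        if k:
            idx = np.argmax(np.abs(components), axis=0)
            signs = np.sign(components[idx, np.arange(k)])
            signs[signs == 0] = 1.0
            components = components * signs
        self.components_ = components
        self.eigenvalues_ = eigenvalues[:k]
        self.all_eigenvalues_ = eigenvalues
        self.explained_variance_ratio_ = (
            self.eigenvalues_ / total_variance if total_variance else self.eigenvalues_)
        self.n_components_ = k
        self.n_samples_ = n
        return self

    def transform(self, X) -> np.ndarray:
        """Project raw input: restandardize with the fitted means/stds, then
        T = Z V_k."""
        Z = self._standardize_new(X)
        return Z @ self.components_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def save(self, path) -> None:
        np.savez(path, means=self.means_, stds=self.stds_,
                 constant_mask=self.constant_mask_, components=self.components_,
                 eigenvalues=self.eigenvalues_,
                 explained_variance_ratio=self.explained_variance_ratio_)

    @classmethod
    def load(cls, path) -> "StandardizedPCA":
        data = np.load(path)
        model = cls(n_components=int(data["components"].shape[1]))
        model.means_ = data["means"]
        model.stds_ = data["stds"]
        model.constant_mask_ = data["constant_mask"]
        model.components_ = data["components"]
        model.eigenvalues_ = data["eigenvalues"]
        model.explained_variance_ratio_ = data["explained_variance_ratio"]
        model.n_components_ = model.components_.shape[1]
        return model


def fit_pca(Z: np.ndarray, k: int | None = None,
            variance_target: float | None = None) -> StandardizedPCA:
    """Fit PCA on an already prepared matrix (standardized internally)."""
    return StandardizedPCA(n_components=k, variance_target=variance_target).fit(Z)


def transform(X: np.ndarray, model: StandardizedPCA) -> np.ndarray:
    return model.transform(X)
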