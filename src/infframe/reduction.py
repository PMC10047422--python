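"""Dimensionality reduction: PCA from first principles, t-SNE/UMAP wrapped.

PCA is computed from the sample covariance eigenproblem of the column-centered
data (via thin SVD, whose right singular vectors are exactly those
eigenvectors).  t-SNE and UMAP are stochastic manifold methods whose internal
objectives are not re-derived here; the established scikit-learn and
umap-learn implementations are wrapped behind a uniform interface that owns
parameter validation, seeding and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .embedding import EmbeddingMatrix

METHODS = ("none", "pca", "tsne", "umap")


@dataclass
class Projection:
    """Low-dimensional coordinates aligned row-for-row with the source matrix."""

    values: np.ndarray
    method: str = "none"
    params: dict[str, Any] = field(default_factory=dict)
    frame_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("projection must be an N x d matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("projection contains non-finite entries")
        if not self.frame_ids:
            self.frame_ids = [f"frame_{i:05d}" for i in range(len(self.values))]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def _values(X) -> np.ndarray:
    if isinstance(X, (EmbeddingMatrix, Projection)):
        return X.values
    return np.asarray(X, dtype=np.float64)


def _frame_ids(X) -> list[str]:
    return list(X.frame_ids) if isinstance(X, (EmbeddingMatrix, Projection)) else []


class PCAReducer(TransformerMixin, BaseEstimator):
    """Principal component analysis via the covariance eigenproblem.

    Fitted attributes: ``components_`` (d x D, rows are the top eigenvectors of
    cov(X) by descending eigenvalue), ``explained_variance_``,
    ``explained_variance_ratio_`` and ``mean_``.  Component signs are fixed so
    the largest-magnitude loading of each component is positive.
    """

    def __init__(self, n_components: int = 50):
        self.n_components = n_components

    def fit(self, X, y=None):
        V = _values(X)
        n, dim = V.shape
        d = self.n_components
        if not 1 <= d <= min(n - 1, dim):
            raise ValueError(f"n_components must lie in [1, {min(n - 1, dim)}]")
        self.mean_ = V.mean(axis=0)
        C = V - self.mean_
        total_var = (C**2).sum() / (n - 1)
        if total_var <= 0:
            raise ValueError("zero-variance input")
        # right singular vectors of centered X == eigenvectors of cov(X)
        _, s, vt = np.linalg.svd(C, full_matrices=False)
        eigvals = s**2 / (n - 1)
        comps = vt[:d]
        flip = np.sign(comps[np.arange(d), np.abs(comps).argmax(axis=1)])
        self.components_ = comps * flip[:, None]
        self.explained_variance_ = eigvals[:d]
        self.explained_variance_ratio_ = eigvals[:d] / total_var
        return self

    def transform(self, X) -> np.ndarray:
        V = _values(X)
        return (V - self.mean_) @ self.components_.T


def pca_project(X, d: int = 50) -> Projection:
    """Project onto the top-``d`` principal components of the sample covariance."""
    est = PCAReducer(n_components=d).fit(X)
    return Projection(
        est.transform(X), "pca",
        {"d": d, "explained_variance_ratio": est.explained_variance_ratio_.tolist()},
        _frame_ids(X),
    )


class EmbeddingReducer(TransformerMixin, BaseEstimator):
    """Uniform front end over {none, pca, tsne, umap}.

    t-SNE and UMAP only support ``fit_transform`` (they are transductive);
    ``method="none"`` passes data through unchanged.  Defaults follow the
    pipeline's study configuration: 50 components for PCA, 2 for the manifold
    methods.
    """

    def __init__(self, method: str = "umap", n_components: int | None = None,
                 perplexity: float = 30.0, learning_rate: float | str = "auto",
                 n_neighbors: int = 15, min_dist: float = 0.1, random_state: int = 0):
        self.method = method
        self.n_components = n_components
        self.perplexity = perplexity
        self.learning_rate = learning_rate
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.random_state = random_state

    def _resolved_dim(self) -> int:
        if self.n_components is not None:
            return self.n_components
        return 50 if self.method == "pca" else 2

    def fit_transform(self, X, y=None) -> np.ndarray:
        V = _values(X)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        d = self._resolved_dim()
        if self.method == "none":
            out = V.copy()
            self.params_ = {}
        elif self.method == "pca":
            est = PCAReducer(n_components=d).fit(V)
            out = est.transform(V)
            self.params_ = {"d": d,
                            "explained_variance_ratio": est.explained_variance_ratio_.tolist()}
        elif self.method == "tsne":
            if not 1 < self.perplexity < len(V):
                raise ValueError("perplexity must lie in (1, n_samples)")
            from sklearn.manifold import TSNE
            est = TSNE(n_components=d, perplexity=self.perplexity,
                       learning_rate=self.learning_rate, init="pca",
                       random_state=self.random_state)
            out = est.fit_transform(V)
            self.params_ = {"d": d, "perplexity": self.perplexity,
                            "learning_rate": self.learning_rate, "impl": "sklearn.manifold.TSNE"}
        else:
            if self.n_neighbors < 2:
                raise ValueError("n_neighbors must be >= 2")
            if not 0.0 <= self.min_dist < 1.0:
                raise ValueError("min_dist must lie in [0, 1)")
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                import umap
                est = umap.UMAP(n_components=d, n_neighbors=self.n_neighbors,
                                min_dist=self.min_dist, random_state=self.random_state)
                out = est.fit_transform(V)
            self.params_ = {"d": d, "n_neighbors": self.n_neighbors,
                            "min_dist": self.min_dist, "impl": f"umap-learn {umap.__version__}"}
        self.embedding_ = np.asarray(out, dtype=np.float64)
        return self.embedding_

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


def reduce(X, method: str = "umap", params: dict | None = None, seed: int = 0) -> Projection:
    """Reduce an embedding matrix with the named method; returns a :class:`Projection`."""
    params = dict(params or {})
    est = EmbeddingReducer(method=method, random_state=seed, **params)
    values = est.fit_transform(X)
    return Projection(values, method, {**est.params_, "seed": seed}, _frame_ids(X))
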