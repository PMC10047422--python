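"""The four clustering methods behind one result contract.

Mini-batch k-means (squared-error criterion), agglomerative linkage
clustering, spectral clustering on the graph Laplacian and DBSCAN are all
wrapped from scikit-learn; this module owns the parameter spaces, seeding,
and the convention that density-unreachable points carry label -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import (
    DBSCAN,
    AgglomerativeClustering,
    MiniBatchKMeans,
    SpectralClustering,
)

from .reduction import Projection

METHODS = ("kmeans", "agglomerative", "spectral", "dbscan")
LINKAGES = ("ward", "average", "complete", "single")


@dataclass
class ClusterResult:
    """Per-frame integer cluster assignments; -1 marks density-method noise."""

    labels: np.ndarray
    method: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) == 0:
            raise ValueError("labels must be a non-empty 1-D integer sequence")
        if self.method != "dbscan" and (self.labels < 0).any():
            raise ValueError(f"{self.method} must not produce noise labels")

    @property
    def k_found(self) -> int:
        return len(set(self.labels[self.labels >= 0]))

    @property
    def n_noise(self) -> int:
        return int((self.labels == -1).sum())


def _values(Y) -> np.ndarray:
    return Y.values if isinstance(Y, Projection) else np.asarray(Y, dtype=float)


class FrameClusterer(ClusterMixin, BaseEstimator):
    """Dispatch to one of {kmeans, agglomerative, spectral, dbscan}.

    ``kmeans`` is the mini-batch variant with seeded initialization.
    ``spectral`` accepts affinity "nearest_neighbors" (with ``n_neighbors``)
    or "rbf" (with ``gamma``).  ``dbscan`` requires ``eps`` and ``min_pts``.
    """

    def __init__(self, method: str = "kmeans", n_clusters: int = 4,
                 linkage: str = "ward", affinity: str = "nearest_neighbors",
                 n_neighbors: int = 10, gamma: float = 1.0,
                 batch_size: int = 1024, n_init: int = 3,
                 eps: float = 0.5, min_pts: int = 5, random_state: int = 0):
        self.method = method
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.affinity = affinity
        self.n_neighbors = n_neighbors
        self.gamma = gamma
        self.batch_size = batch_size
        self.n_init = n_init
        self.eps = eps
        self.min_pts = min_pts
        self.random_state = random_state

    def fit(self, X, y=None):
        V = _values(X)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.method != "dbscan":
            if self.n_clusters is None:
                raise ValueError(f"{self.method} requires n_clusters")
            if not 1 <= self.n_clusters <= len(V):
                raise ValueError("n_clusters must lie in [1, n_samples]")
        if self.method == "kmeans":
            est = MiniBatchKMeans(n_clusters=self.n_clusters, batch_size=self.batch_size,
                                  n_init=self.n_init, random_state=self.random_state)
        elif self.method == "agglomerative":
            if self.linkage not in LINKAGES:
                raise ValueError(f"linkage must be one of {LINKAGES}")
            est = AgglomerativeClustering(n_clusters=self.n_clusters, linkage=self.linkage)
        elif self.method == "spectral":
            if self.n_clusters == 1:
                self.labels_ = np.zeros(len(V), dtype=int)
                return self
            kwargs = {"affinity": self.affinity}
            if self.affinity == "nearest_neighbors":
                kwargs["n_neighbors"] = self.n_neighbors
            else:
                kwargs["gamma"] = self.gamma
            est = SpectralClustering(n_clusters=self.n_clusters,
                                     random_state=self.random_state,
                                     assign_labels="kmeans", **kwargs)
        else:
            if self.eps is None or self.eps <= 0:
                raise ValueError("dbscan requires eps > 0")
            if self.min_pts is None or self.min_pts < 1:
                raise ValueError("dbscan requires min_pts >= 1")
            est = DBSCAN(eps=self.eps, min_samples=self.min_pts)
        self.labels_ = np.asarray(est.fit_predict(V), dtype=int)
        return self


def cluster(Y, method: str = "kmeans", params: dict | None = None,
            seed: int = 0) -> ClusterResult:
    """Run one clustering method over projected features."""
    params = dict(params or {})
    est = FrameClusterer(method=method, random_state=seed, **params)
    labels = est.fit(Y).labels_
    return ClusterResult(labels, method, {**params, "seed": seed})


def squared_error(Y, labels) -> float:
    """Within-cluster sum of squared distances to centroids (k-means objective)."""
    V = _values(Y)
    labels = np.asarray(labels)
    total = 0.0
    for c in np.unique(labels[labels >= 0]):
        pts = V[labels == c]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(total)


def default_search_space(method: str, Y=None) -> dict[str, tuple]:
    """Hyperparameter space for each method, used by the tuning module.

    Each entry maps a parameter name to a spec tuple: ``("int", lo, hi)``,
    ``("log", lo, hi)`` (continuous, log-uniform) or ``("choice", options)``.
    The DBSCAN eps range is scaled to the data when ``Y`` is given: a
    log-range around the median nearest-neighbor distance.
    """
    if method == "kmeans":
        return {"batch_size": ("int", 32, 1024), "n_init": ("int", 1, 10)}
    if method == "agglomerative":
        return {"linkage": ("choice", list(LINKAGES))}
    if method == "spectral":
        return {"affinity": ("choice", ["nearest_neighbors", "rbf"]),
                "n_neighbors": ("int", 5, 30), "gamma": ("log", 1e-3, 10.0)}
    if method == "dbscan":
        lo, hi = 1e-3, 10.0
        if Y is not None:
            from sklearn.neighbors import NearestNeighbors
            V = _values(Y)
            sub = V[:: max(1, len(V) // 500)]
            d, _ = NearestNeighbors(n_neighbors=2).fit(sub).kneighbors(sub)
            med = float(np.median(d[:, 1]))
            med = max(med, 1e-6)
            lo, hi = med / 10.0, med * 10.0
        return {"eps": ("log", lo, hi), "min_pts": ("int", 3, 20)}
    raise ValueError(f"unknown method {method!r}")
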