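"""Automatic cluster labeling: maximum-intersection bijection.

Clusters produced by an unsupervised method carry arbitrary integer ids; to
score them as a classifier each cluster must be assigned a ground-truth
category.  The greedy rule maps each cluster (in ascending id order) to the
category it intersects most; because the greedy pass can collide — two
clusters claiming one category, which breaks the required one-to-one
correspondence — a collision triggers exhaustive maximization over all K!
bijections and the result is flagged ``mode="optimal"``.

Noise points (cluster id -1) are excluded from the contingency table and the
mapping; downstream they count as errors for their true category.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .clustering import ClusterResult
from .synthdata import CATEGORIES


def _category_order(categories) -> list:
    """Stable category order: the canonical (I, B, S, U) first, then sorted extras."""
    cats = set(categories)
    ordered = [c for c in CATEGORIES if c in cats]
    ordered += sorted(c for c in cats if c not in CATEGORIES)
    return ordered


@dataclass
class ContingencyTable:
    """K x G intersection counts between clusters (rows) and categories (columns)."""

    counts: np.ndarray
    cluster_ids: list[int]
    category_ids: list
    n_noise: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.cluster_ids), len(self.category_ids)):
            raise ValueError("counts shape must match cluster/category ids")


@dataclass
class LabelMapping:
    """Injective map from cluster id to category, with its total intersection."""

    map: dict[int, object]
    total_intersection: int
    mode: str  # "greedy" | "optimal"
    n_noise: int = 0
    unassigned: object = field(default="unassigned")

    def apply(self, cluster_labels) -> list:
        """Translate integer cluster labels to categories; noise -> unassigned."""
        labels = np.asarray(cluster_labels)
        return [self.map.get(int(c), self.unassigned) for c in labels]


def contingency(clusters, truth) -> ContingencyTable:
    """Count frames per (cluster, true category); noise rows are excluded."""
    labels = clusters.labels if isinstance(clusters, ClusterResult) else np.asarray(clusters)
    truth = list(truth)
    if len(labels) != len(truth):
        raise ValueError("cluster labels and truth must have equal length")
    if len(labels) == 0:
        raise ValueError("empty input")
    cats = _category_order(truth)
    cat_index = {c: j for j, c in enumerate(cats)}
    cluster_ids = sorted(set(int(c) for c in labels if c >= 0))
    cl_index = {c: i for i, c in enumerate(cluster_ids)}
    counts = np.zeros((len(cluster_ids), len(cats)), dtype=int)
    n_noise = 0
    for c, t in zip(labels, truth):
        if c < 0:
            n_noise += 1
            continue
        counts[cl_index[int(c)], cat_index[t]] += 1
    return ContingencyTable(counts, cluster_ids, cats, n_noise)


def greedy_label_map(T: ContingencyTable) -> LabelMapping:
    """Greedy per-cluster argmax assignment; collisions repaired exhaustively.

    Iterates clusters in ascending id order, mapping each to the category with
    the largest intersection (ties broken to the lowest category index).  If
    two clusters claim the same category the greedy result is not a bijection;
    the mapping then falls back to :func:`optimal_label_map` and is flagged
    ``mode="optimal"``.
    """
    K, G = T.counts.shape
    if K != G:
        raise ValueError(
            f"need as many clusters as categories (got {K} clusters, {G} categories); "
            "cluster-count determination failed")
    mapping = {}
    for i, cid in enumerate(T.cluster_ids):
        j = int(np.argmax(T.counts[i]))  # argmax takes the first (lowest) index on ties
        mapping[cid] = T.category_ids[j]
    if len(set(mapping.values())) < K:
        return optimal_label_map(T)
    total = int(sum(T.counts[i, T.category_ids.index(mapping[cid])]
                    for i, cid in enumerate(T.cluster_ids)))
    return LabelMapping(mapping, total, "greedy", T.n_noise)


def optimal_label_map(T: ContingencyTable) -> LabelMapping:
    """Exhaustive maximizer over all K! bijections (K <= 10).

    Ties between equally good bijections are broken by lexicographic order of
    the category assignment sequence (clusters in ascending id order).
    """
    K, G = T.counts.shape
    if K != G:
        raise ValueError(f"need a square table (got {K} x {G})")
    if K > 10:
        raise ValueError("exhaustive search is limited to K <= 10")
    best_perm, best_total = None, -1
    for perm in itertools.permutations(range(G)):
        total = int(T.counts[np.arange(K), perm].sum())
        if total > best_total:  # strict: permutations iterate in lex order
            best_perm, best_total = perm, total
    mapping = {cid: T.category_ids[j] for cid, j in zip(T.cluster_ids, best_perm)}
    return LabelMapping(mapping, best_total, "optimal", T.n_noise)


class ClusterLabelMapper(BaseEstimator):
    """Estimator facade: fit(cluster_labels, truth) learns the bijection.

    Fitted attributes: ``contingency_``, ``mapping_``, ``mode_``,
    ``total_intersection_``.  ``predict`` translates cluster ids to categories
    (noise becomes ``"unassigned"``).
    """

    def __init__(self, strategy: str = "greedy"):
        self.strategy = strategy

    def fit(self, X, y):
        T = contingency(X, y)
        if self.strategy == "greedy":
            m = greedy_label_map(T)
        elif self.strategy == "optimal":
            m = optimal_label_map(T)
        else:
            raise ValueError("strategy must be 'greedy' or 'optimal'")
        self.contingency_ = T
        self.mapping_ = m
        self.mode_ = m.mode
        self.total_intersection_ = m.total_intersection
        return self

    def predict(self, X) -> list:
        labels = X.labels if isinstance(X, ClusterResult) else X
        return self.mapping_.apply(labels)
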