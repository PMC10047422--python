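"""Scoring the clustering-as-classifier: confusion metrics, ROC/AUC,
internal validity indices, robust summaries and exact paired tests.

Classification metrics are one-vs-rest per category.  The Calinski-Harabasz
index and silhouette score are computed directly from their definitions
(between/within dispersion ratio; (b - a) / max(a, b)) rather than wrapped,
because downstream tests treat library implementations as independent
cross-checks.  Summaries use the midpoint median and Tukey-hinge IQR — the
quartile convention under which the published summary cells reproduce
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .labeling import LabelMapping, _category_order

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# confusion-based metrics

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class MetricsReport:
    """Per-category precision/recall/F1 with medians, Tukey IQRs and accuracy."""

    categories: list
    precision: dict
    recall: dict
    f1: dict
    accuracy: float
    median: dict = field(default_factory=dict)
    iqr: dict = field(default_factory=dict)
    auc: dict | None = None
    mean_auc: float | None = None

    def as_dict(self) -> dict:
        out = {
            "categories": list(self.categories),
            "precision": dict(self.precision),
            "recall": dict(self.recall),
            "f1": dict(self.f1),
            "accuracy": self.accuracy,
            "median": dict(self.median),
            "iqr": dict(self.iqr),
        }
        if self.auc is not None:
            out["auc"] = dict(self.auc)
            out["mean_auc"] = self.mean_auc
        return out


def confusion_counts(predicted, truth, categories=None) -> dict:
    """One-vs-rest TP/FP/FN/TN per category.

    ``predicted`` uses the category vocabulary; the reserved ``unassigned``
    value (density-method noise after mapping) is never a true positive and
    counts as a false negative for the point's true category.
    """
    predicted, truth = list(predicted), list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    cats = categories if categories is not None else _category_order(truth)
    n = len(truth)
    out = {}
    for c in cats:
        tp = sum(1 for p, t in zip(predicted, truth) if p == c and t == c)
        fp = sum(1 for p, t in zip(predicted, truth) if p == c and t != c)
        fn = sum(1 for p, t in zip(predicted, truth) if p != c and t == c)
        out[c] = ConfusionCounts(tp, fp, fn, n - tp - fp - fn)
    return out


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def classification_metrics(predicted, truth, scores=None, categories=None) -> MetricsReport:
    """Precision, sensitivity (recall) and F1 per category, plus summaries.

    When a score matrix is given (columns aligned with the category order),
    one-vs-rest AUCs and their mean are included.
    """
    cats = categories if categories is not None else _category_order(truth)
    counts = confusion_counts(predicted, truth, cats)
    prec = {c: _safe_div(cc.tp, cc.tp + cc.fp) for c, cc in counts.items()}
    rec = {c: _safe_div(cc.tp, cc.tp + cc.fn) for c, cc in counts.items()}
    f1 = {c: _safe_div(2 * cc.tp, 2 * cc.tp + cc.fp + cc.fn) for c, cc in counts.items()}
    acc = sum(1 for p, t in zip(predicted, truth) if p == t) / len(list(truth))
    report = MetricsReport(list(cats), prec, rec, f1, acc)
    if len(cats) >= 2:
        for name, d in (("precision", prec), ("recall", rec), ("f1", f1)):
            m, q = median_and_iqr([d[c] for c in cats])
            report.median[name] = m
            report.iqr[name] = q
    if scores is not None:
        report.auc = roc_auc(scores, truth, cats)
        report.mean_auc = float(np.mean(list(report.auc.values())))
    return report


# ---------------------------------------------------------------------------
# summaries

def _tukey_hinges(sorted_vals: Sequence) -> tuple:
    n = len(sorted_vals)
    half = (n + 1) // 2  # median included in both halves when n is odd
    lower, upper = sorted_vals[:half], sorted_vals[n - half:]

    def mid(vals):
        m = len(vals)
        if m % 2:
            return vals[m // 2]
        return (vals[m // 2 - 1] + vals[m // 2]) / 2

    return mid(lower), mid(upper)


def median_and_iqr(values: Sequence[float]) -> tuple[float, float]:
    """Midpoint median and Tukey-hinge IQR (upper hinge minus lower hinge)."""
    vals = sorted(float(v) for v in values)
    if len(vals) < 2:
        raise ValueError("need at least 2 values")
    lh, uh = _tukey_hinges(vals)
    return float(np.median(vals)), float(uh - lh)


def rounded_summary(values: Sequence[float], ndigits: int = 2) -> tuple[float, float]:
    """median_and_iqr in exact decimal arithmetic, rounded half-up.

    Published tables print values to two decimals; float arithmetic can land
    an exact .005 boundary on the wrong side (0.845 - 0.76 -> 0.0849...), so
    table comparisons go through Fractions.
    """
    vals = sorted(Fraction(str(v)) for v in values)
    if len(vals) < 2:
        raise ValueError("need at least 2 values")
    lh, uh = _tukey_hinges(vals)
    n = len(vals)
    med = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2

    def round_half_up(x: Fraction) -> float:
        scale = 10**ndigits
        return float((x * scale + Fraction(1, 2)).__floor__()) / scale

    return round_half_up(med), round_half_up(uh - lh)


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(scores, truth, categories=None) -> dict:
    """One-vs-rest AUC per category from the rank (Mann-Whitney) statistic.

    Ties in scores are handled with midranks, so constant scores give 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    truth = list(truth)
    cats = categories if categories is not None else _category_order(truth)
    if scores.shape != (len(truth), len(cats)):
        raise ValueError("scores must be N x G aligned with the category order")
    out = {}
    for j, c in enumerate(cats):
        pos = np.array([t == c for t in truth])
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0:
            raise ValueError(f"category {c!r} absent from truth")
        if n_neg == 0:
            raise ValueError(f"category {c!r} has no negatives")
        ranks = rankdata(scores[:, j])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
        out[c] = float(u / (n_pos * n_neg))
    return out


def centroid_distance_scores(Y, cluster_labels, mapping: LabelMapping,
                             categories=None) -> np.ndarray:
    """Continuous one-vs-rest scores for a hard clustering.

    Score of point i for category c is the negative Euclidean distance from
    y_i to the centroid of the cluster mapped to c, standardized per category
    (an affine per-column transform, so AUCs are unaffected).  This is the
    package's construction for drawing ROC curves from hard cluster
    assignments.
    """
    from .reduction import Projection

    V = Y.values if isinstance(Y, Projection) else np.asarray(Y, dtype=float)
    labels = np.asarray(cluster_labels)
    cats = categories if categories is not None else _category_order(mapping.map.values())
    cat_to_cluster = {cat: cid for cid, cat in mapping.map.items()}
    cols = []
    for c in cats:
        cid = cat_to_cluster.get(c)
        if cid is None or not (labels == cid).any():
            cols.append(np.zeros(len(V)))
            continue
        centroid = V[labels == cid].mean(axis=0)
        d = -np.linalg.norm(V - centroid, axis=1)
        sd = d.std()
        cols.append((d - d.mean()) / sd if sd > 0 else d - d.mean())
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# internal validity indices

def silhouette_values(Y, labels) -> np.ndarray:
    """Per-point silhouette (b - a) / max(a, b).

    ``a`` is the mean distance to the other members of the point's cluster,
    ``b`` the smallest mean distance to the members of any other cluster.
    Points in singleton clusters get silhouette 0.
    """
    from .reduction import Projection

    V = Y.values if isinstance(Y, Projection) else np.asarray(Y, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = cdist(V, V)
    s = np.zeros(len(V))
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for i in range(len(V)):
        own = members[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (len(own) - 1)
        b = min(D[i, members[c]].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s


def silhouette(Y, labels) -> float:
    """Average silhouette over all points."""
    return float(silhouette_values(Y, labels).mean())


def calinski_harabasz(Y, labels) -> float:
    """Variance-ratio criterion: (BGSS/(K-1)) / (WGSS/(N-K)).

    BGSS is the size-weighted squared distance of cluster centroids from the
    grand centroid, WGSS the pooled within-cluster squared distance.  A
    perfectly tight clustering (WGSS = 0) returns +inf.
    """
    from .reduction import Projection

    V = Y.values if isinstance(Y, Projection) else np.asarray(Y, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = len(V), len(uniq)
    if k < 2 or k >= n:
        raise ValueError("need 2 <= K < N")
    grand = V.mean(axis=0)
    bgss = wgss = 0.0
    for c in uniq:
        pts = V[labels == c]
        centroid = pts.mean(axis=0)
        bgss += len(pts) * float(((centroid - grand) ** 2).sum())
        wgss += float(((pts - centroid) ** 2).sum())
    if wgss == 0.0:
        import warnings

        warnings.warn("within-cluster dispersion is zero; CH index is infinite")
        return float("inf")
    return (bgss / (k - 1)) / (wgss / (n - k))


def determine_cluster_number(Y, k_range=range(2, 7), clusterer=None, seed: int = 0):
    """Sweep candidate cluster counts and pick the CH-index argmax.

    ``clusterer(k, V) -> labels`` defaults to seeded mini-batch k-means.
    Returns ``(chosen_k, {k: ch_score})``; ties resolve to the smallest k.
    """
    from .reduction import Projection

    V = Y.values if isinstance(Y, Projection) else np.asarray(Y, dtype=float)
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k range")
    if clusterer is None:
        from .clustering import FrameClusterer

        def clusterer(k, V):
            return FrameClusterer(method="kmeans", n_clusters=k,
                                  random_state=seed).fit(V).labels_

    scores = {}
    for k in ks:
        labels = clusterer(k, V)
        scores[k] = calinski_harabasz(V, labels)
    chosen = max(sorted(scores), key=lambda k: scores[k])
    return chosen, scores


# ---------------------------------------------------------------------------
# exact paired Wilcoxon signed-rank test

@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_nonzero: int
    all_zero: bool = False


def wilcoxon_exact(paired_a, paired_b) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test for small paired samples.

    Zero differences are dropped; tied absolute differences get midranks; the
    statistic is the smaller signed-rank sum; the p-value enumerates all 2^n
    sign assignments and is capped at 1.  Suitable for n <= 15 pairs.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if not 2 <= len(a) <= 15:
        raise ValueError("need between 2 and 15 pairs")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, all_zero=True)
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    # exact null: each sign pattern equally likely; W = rank sum of positives
    count = 0
    for pattern in range(2**n):
        w_p = sum(ranks[i] for i in range(n) if pattern >> i & 1)
        if w_p <= w + 1e-12:
            count += 1
    p = min(1.0, 2.0 * count / 2**n)
    return WilcoxonResult(w, p, n)
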