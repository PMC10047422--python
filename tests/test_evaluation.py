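import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

import infframe as iff
from infframe import benchmarks


# ---------------------------------------------------------------------------
# confusion-based metrics

def test_metrics_from_direct_counts():
    # one category with TP=9, FP=1, FN=3 among 20 points
    truth = ["a"] * 12 + ["b"] * 8
    pred = ["a"] * 9 + ["b"] * 3 + ["a"] + ["b"] * 7
    rep = iff.classification_metrics(pred, truth)
    assert rep.precision["a"] == pytest.approx(0.9)
    assert rep.recall["a"] == pytest.approx(0.75)
    assert rep.f1["a"] == pytest.approx(18 / 22)


def test_perfect_prediction_all_ones():
    truth = ["a", "b", "c"] * 5
    rep = iff.classification_metrics(truth, truth)
    assert all(v == 1.0 for v in rep.precision.values())
    assert all(v == 1.0 for v in rep.recall.values())
    assert rep.accuracy == 1.0


def test_zero_denominator_convention_returns_zero():
    truth = ["a"] * 5 + ["b"] * 5
    pred = ["b"] * 10  # category "a" never predicted: TP=0, FP=0 -> precision 0
    rep = iff.classification_metrics(pred, truth)
    assert rep.precision["a"] == 0.0
    assert rep.recall["a"] == 0.0
    assert rep.f1["a"] == 0.0


def test_unassigned_counts_as_miss_not_hit():
    truth = ["a", "a", "b", "b"]
    pred = ["a", "unassigned", "b", "b"]
    rep = iff.classification_metrics(pred, truth, categories=["a", "b"])
    assert rep.recall["a"] == pytest.approx(0.5)
    assert rep.precision["a"] == 1.0


def test_f1_is_harmonic_mean_of_precision_and_recall():
    rng = np.random.default_rng(0)
    truth = [f"c{t}" for t in rng.integers(0, 4, 300)]
    pred = [f"c{t}" for t in rng.integers(0, 4, 300)]
    rep = iff.classification_metrics(pred, truth)
    for c in rep.categories:
        p, r = rep.precision[c], rep.recall[c]
        expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        assert rep.f1[c] == pytest.approx(expected)


def test_metrics_length_mismatch_rejected():
    with pytest.raises(ValueError):
        iff.classification_metrics(["a"], ["a", "b"])


# ---------------------------------------------------------------------------
# summaries

def test_median_and_iqr_published_rows():
    med, iqr = iff.rounded_summary([0.83, 0.91, 0.62, 0.85])
    assert (med, iqr) == (0.84, 0.16)
    med, iqr = iff.rounded_summary([0.98, 0.95, 0.86, 0.93])
    assert (med, iqr) == (0.94, 0.07)


def test_median_and_iqr_hinge_rule_odd_length():
    med, iqr = iff.median_and_iqr([1, 2, 3, 4, 5])
    assert med == 3.0
    assert iqr == 2.0  # hinges 2 and 4, median counted in both halves


def test_median_and_iqr_needs_two_values():
    with pytest.raises(ValueError):
        iff.median_and_iqr([0.5])


def test_rounded_summary_reproduces_umap_kmeans_column():
    assert iff.rounded_summary(benchmarks.UMAP_KMEANS["precision"]) == (0.92, 0.07)
    assert iff.rounded_summary(benchmarks.UMAP_KMEANS["recall"]) == (0.94, 0.07)
    assert iff.rounded_summary(benchmarks.UMAP_KMEANS["f1"]) == (0.93, 0.05)


# ---------------------------------------------------------------------------
# ROC / AUC

def test_auc_perfectly_separating_scores():
    truth = ["a", "a", "b", "b"]
    scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
    auc = iff.roc_auc(scores, truth, ["a", "b"])
    assert auc == {"a": 1.0, "b": 1.0}


def test_auc_constant_scores_is_half():
    truth = ["a", "a", "b", "b"]
    auc = iff.roc_auc(np.zeros((4, 2)), truth, ["a", "b"])
    assert auc == {"a": 0.5, "b": 0.5}


def test_auc_matches_pair_enumeration():
    """Oracle: count concordant positive-negative pairs directly."""
    scores = np.array([0.1, 0.4, 0.35, 0.8])
    truth = ["n", "n", "p", "p"]
    auc = iff.roc_auc(np.column_stack([-scores, scores]), truth, ["n", "p"])
    assert auc["p"] == pytest.approx(0.75)  # pairs: (0.35 vs 0.1, 0.4), (0.8 vs both)


def test_auc_requires_category_presence():
    with pytest.raises(ValueError):
        iff.roc_auc(np.zeros((3, 2)), ["a", "a", "a"], ["a", "b"])


# ---------------------------------------------------------------------------
# validity indices

def test_silhouette_hand_computed_example():
    Y = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = [0, 0, 1, 1]
    s = iff.silhouette_values(Y, labels)
    assert s[0] == pytest.approx((10.5 - 1.0) / 10.5)


def test_silhouette_identical_overlapping_clusters_near_zero():
    pts = np.random.default_rng(0).normal(size=(30, 2))
    Y = np.vstack([pts, pts])
    labels = [0] * 30 + [1] * 30
    assert abs(iff.silhouette(Y, labels)) < 0.05


def test_silhouette_well_separated_blobs_near_one():
    X, labels = iff.generate_blob_embeddings(iff.BlobSpec(4, 60, 10, 50.0, 1.0, seed=1))
    assert iff.silhouette(X, labels) > 0.9


def test_silhouette_singleton_cluster_scores_zero():
    Y = np.array([[0.0], [1.0], [10.0]])
    s = iff.silhouette_values(Y, [0, 0, 1])
    assert s[2] == 0.0


def test_silhouette_single_cluster_rejected():
    with pytest.raises(ValueError):
        iff.silhouette(np.zeros((5, 2)), [0] * 5)


def test_silhouette_matches_library_cross_check():
    rng = np.random.default_rng(3)
    for _ in range(10):
        Y = rng.normal(size=(25, 3))
        labels = rng.integers(0, 3, 25)
        if len(np.unique(labels)) < 2:
            continue
        ours = iff.silhouette_values(Y, labels)
        ref = silhouette_samples(Y, labels)
        assert np.allclose(ours, ref, rtol=1e-9, atol=1e-12)


def test_calinski_harabasz_hand_computed_example():
    Y = np.array([[0.0], [1.0], [10.0], [11.0]])
    assert iff.calinski_harabasz(Y, [0, 0, 1, 1]) == pytest.approx(200.0)


def test_calinski_harabasz_guards():
    Y = np.arange(4.0).reshape(-1, 1)
    with pytest.raises(ValueError):
        iff.calinski_harabasz(Y, [0, 1, 2, 3])  # K = N
    with pytest.raises(ValueError):
        iff.calinski_harabasz(Y, [0, 0, 0, 0])  # K = 1


def test_calinski_harabasz_grows_with_separation():
    prev = 0.0
    for sep in (5.0, 10.0, 20.0):
        X, labels = iff.generate_blob_embeddings(iff.BlobSpec(4, 50, 10, sep, 1.0, seed=2))
        ch = iff.calinski_harabasz(X, labels)
        assert ch > prev
        prev = ch


def test_calinski_harabasz_matches_library_cross_check():
    rng = np.random.default_rng(4)
    for _ in range(10):
        Y = rng.normal(size=(28, 4))
        labels = rng.integers(0, 4, 28)
        if len(np.unique(labels)) < 2:
            continue
        assert iff.calinski_harabasz(Y, labels) == pytest.approx(
            calinski_harabasz_score(Y, labels), rel=1e-9)


def test_cluster_number_sweep_finds_true_k():
    for true_k in (3, 4):
        X, _ = iff.generate_blob_embeddings(iff.BlobSpec(true_k, 80, 10, 20.0, 1.0, seed=6))
        chosen, scores = iff.determine_cluster_number(X, range(2, 7), seed=0)
        assert chosen == true_k
        assert set(scores) == {2, 3, 4, 5, 6}


def test_cluster_number_trivial_range():
    X, _ = iff.generate_blob_embeddings(iff.BlobSpec(4, 30, 5, 20.0, 1.0, seed=0))
    chosen, _ = iff.determine_cluster_number(X, [2], seed=0)
    assert chosen == 2


def test_cluster_number_empty_range_rejected():
    with pytest.raises(ValueError):
        iff.determine_cluster_number(np.zeros((10, 2)), [])


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank test

def test_wilcoxon_published_comparisons():
    ours = benchmarks.RECALL["umap_agglo"]
    assert iff.wilcoxon_exact(ours, benchmarks.RECALL["svm"]).p_value == pytest.approx(0.125)
    assert iff.wilcoxon_exact(ours, benchmarks.RECALL["vgg16"]).p_value == pytest.approx(0.625)
    assert iff.wilcoxon_exact(ours, benchmarks.RECALL["squeezenet"]).p_value == pytest.approx(1.0)


def test_wilcoxon_identical_vectors():
    res = iff.wilcoxon_exact([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
    assert res.p_value == 1.0
    assert res.all_zero


def test_wilcoxon_agrees_with_scipy_exact_enumeration():
    rng = np.random.default_rng(9)
    for _ in range(30):
        n = int(rng.integers(4, 11))
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        ours = iff.wilcoxon_exact(a, b).p_value
        ref = scipy.stats.wilcoxon(a, b, mode="exact", alternative="two-sided").pvalue
        assert ours == pytest.approx(ref)


def test_wilcoxon_input_validation():
    with pytest.raises(ValueError):
        iff.wilcoxon_exact([1.0], [2.0])
    with pytest.raises(ValueError):
        iff.wilcoxon_exact(list(range(16)), list(range(16)))
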