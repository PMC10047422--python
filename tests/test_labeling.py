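import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import infframe as iff
from infframe.labeling import ClusterLabelMapper, ContingencyTable


def _table(counts):
    counts = np.asarray(counts)
    k, g = counts.shape
    return ContingencyTable(counts, list(range(k)), [f"cat{j}" for j in range(g)])


def test_contingency_perfect_clustering_is_permuted_diagonal(blob_data):
    X, truth = blob_data
    result = iff.cluster(X, "kmeans", {"n_clusters": 4}, seed=0)
    T = iff.contingency(result, [str(t) for t in truth])
    assert T.counts.sum() == 720
    assert sorted(T.counts.max(axis=1)) == [180] * 4
    assert (T.counts.sum(axis=1) == 180).all()


def test_contingency_single_cluster_collapses_to_category_counts():
    T = iff.contingency(np.zeros(10, dtype=int), ["a"] * 4 + ["b"] * 6)
    assert T.counts.shape == (1, 2)
    assert sorted(T.counts[0].tolist()) == [4, 6]


def test_contingency_excludes_noise_points():
    labels = np.array([0, 0, 1, 1, -1, -1, -1])
    truth = ["a", "a", "b", "b", "a", "b", "b"]
    T = iff.contingency(labels, truth)
    assert T.counts.sum() == 4
    assert T.n_noise == 3


def test_contingency_input_validation():
    with pytest.raises(ValueError):
        iff.contingency(np.array([0, 1]), ["a"])
    with pytest.raises(ValueError):
        iff.contingency(np.array([], dtype=int), [])


def test_greedy_diagonal_dominant_maps_identity():
    counts = np.full((4, 4), 10)
    np.fill_diagonal(counts, 180)
    m = iff.greedy_label_map(_table(counts))
    assert m.mode == "greedy"
    assert m.map == {i: f"cat{i}" for i in range(4)}
    assert m.total_intersection == 4 * 180


def test_greedy_collision_repaired_exhaustively():
    """Both clusters prefer category 0; the bijection constraint forces the swap."""
    m = iff.greedy_label_map(_table([[100, 80], [90, 10]]))
    assert m.mode == "optimal"
    assert m.map == {0: "cat1", 1: "cat0"}
    assert m.total_intersection == 170


def test_greedy_tie_broken_to_lowest_category_index():
    m = iff.greedy_label_map(_table([[5, 5], [0, 10]]))
    assert m.mode == "greedy"
    assert m.map == {0: "cat0", 1: "cat1"}


def test_greedy_requires_square_table():
    with pytest.raises(ValueError):
        iff.greedy_label_map(_table([[3, 4]]))


def test_optimal_recovers_scaled_permutation_matrix():
    perm = [2, 0, 3, 1]
    counts = np.zeros((4, 4), dtype=int)
    for i, j in enumerate(perm):
        counts[i, j] = 180
    m = iff.optimal_label_map(_table(counts))
    assert m.map == {i: f"cat{j}" for i, j in enumerate(perm)}
    assert m.total_intersection == 720


def test_optimal_all_equal_table_breaks_ties_lexicographically():
    m = iff.optimal_label_map(_table(np.full((3, 3), 7)))
    assert m.map == {0: "cat0", 1: "cat1", 2: "cat2"}


def test_optimal_rejects_large_or_rectangular_tables():
    with pytest.raises(ValueError):
        iff.optimal_label_map(_table(np.ones((11, 11), dtype=int)))
    with pytest.raises(ValueError):
        iff.optimal_label_map(_table(np.ones((2, 3), dtype=int)))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 200), min_size=16, max_size=16))
def test_optimal_bounds_on_random_tables(flat):
    """optimal >= greedy everywhere, and never exceeds the unconstrained row-argmax sum."""
    T = _table(np.array(flat).reshape(4, 4))
    m_opt = iff.optimal_label_map(T)
    m_greedy = iff.greedy_label_map(T)
    assert m_greedy.total_intersection <= m_opt.total_intersection
    assert m_opt.total_intersection <= int(T.counts.max(axis=1).sum())


def test_greedy_equals_oracle_whenever_bijective():
    rng = np.random.default_rng(123)
    agree = checked = 0
    for _ in range(1000):
        T = _table(rng.integers(0, 200, size=(4, 4)))
        m = iff.greedy_label_map(T)
        if m.mode == "greedy":
            checked += 1
            agree += m.total_intersection == iff.optimal_label_map(T).total_intersection
    assert checked > 50
    assert agree == checked


def test_mapping_accuracy_identity(blob_data):
    """Applying the map and recounting gives accuracy = total / (N - noise)."""
    X, truth = blob_data
    truth = [str(t) for t in truth]
    labels = iff.cluster(X, "kmeans", {"n_clusters": 4}, seed=0).labels.copy()
    labels[:10] = -1  # simulate noise
    m = iff.greedy_label_map(iff.contingency(labels, truth))
    mapped = m.apply(labels)
    correct = sum(1 for p, t in zip(mapped, truth) if p == t)
    assert correct == m.total_intersection
    assert m.n_noise == 10


def test_mapping_invariant_to_cluster_id_permutation():
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 4, 200)
    truth = [f"cat{t}" for t in rng.integers(0, 4, 200)]
    m1 = iff.greedy_label_map(iff.contingency(labels, truth))
    perm = np.array([2, 3, 1, 0])
    m2 = iff.greedy_label_map(iff.contingency(perm[labels], truth))
    assert m1.total_intersection == m2.total_intersection
    assert all(m2.map[perm[c]] == cat for c, cat in m1.map.items())


def test_estimator_facade_predicts_categories(blob_data):
    X, truth = blob_data
    truth = [str(t) for t in truth]
    result = iff.cluster(X, "kmeans", {"n_clusters": 4}, seed=0)
    est = ClusterLabelMapper().fit(result, truth)
    assert est.mode_ in ("greedy", "optimal")
    assert est.predict(result) == est.mapping_.apply(result.labels)
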