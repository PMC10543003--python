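"""Trajectory clustering: filters, linkage oracle, node-depth cuts, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from brewtime.cluster import (
    ClusterAssignment,
    cut_by_node_depth,
    cut_to_n_clusters,
    enrich_terms,
    hcluster,
    twofold_filter,
)
from brewtime.containers import AbundanceMatrix, ValidationError
from brewtime.quantify import row_mean_normalize, sum_replicates


def _matrix(values, state="row_mean_normalized", proteins=None):
    arr = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(arr.shape[0])]
    cols = [f"t{j}" for j in range(arr.shape[1])]
    return AbundanceMatrix(pd.DataFrame(arr, index=proteins, columns=cols), state=state)


# ---------------------------------------------------------------------------
# Two-fold filter
# ---------------------------------------------------------------------------

def test_twofold_filter_boundary_inclusive():
    m = _matrix([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.9, -0.9, 0.0], [-1.2, 0.3, 0.0]])
    out = twofold_filter(m)
    assert list(out.data.index) == ["P1", "P3"]


def test_twofold_filter_requires_row_mean_normalized():
    with pytest.raises(ValidationError):
        twofold_filter(_matrix([[1.0, 0.0]], state="raw"))


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def brute_force_average_linkage(dist: np.ndarray):
    """O(n^3) agglomeration; cluster distance = mean of original pairwise
    distances.  Returns [(frozenset_of_leaves, height), ...] per merge."""
    clusters = {i: frozenset([i]) for i in range(dist.shape[0])}
    merges = []
    next_id = dist.shape[0]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[next_id] = merged
        merges.append((merged, d))
        next_id += 1
    return merges


def test_identical_rows_merge_first_at_height_zero(rng):
    vals = rng.normal(size=(5, 8))
    vals[3] = vals[1]
    tree = hcluster(_matrix(vals))
    first = tree.linkage[0]
    assert {int(first[0]), int(first[1])} == {1, 3}
    assert first[2] == pytest.approx(0.0, abs=1e-12)


def test_anticorrelated_rows_distance_two():
    vals = np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1], [1.0, 5, 2, 8]])
    tree = hcluster(_matrix(vals))
    # the anticorrelated pair merges last, at average distance including 2
    from brewtime.qc import protein_correlation

    cm = protein_correlation(_matrix(vals))
    assert 1 - cm.values.loc["P0", "P1"] == pytest.approx(2.0)


def test_linkage_matches_brute_force_oracle(rng):
    for _ in range(5):
        vals = rng.normal(size=(6, 10))
        m = _matrix(vals)
        tree = hcluster(m)
        corr = np.corrcoef(vals)
        dist = 1 - corr
        np.fill_diagonal(dist, 0.0)
        expected = brute_force_average_linkage(dist)
        n = vals.shape[0]

        def leaves_of(node, Z=tree.linkage):
            if node < n:
                return frozenset([node])
            left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
            return leaves_of(left) | leaves_of(right)

        got = [
            (leaves_of(n + k), tree.linkage[k, 2]) for k in range(tree.linkage.shape[0])
        ]
        for (gl, gh), (el, eh) in zip(got, expected):
            assert gl == el
            assert gh == pytest.approx(eh, abs=1e-10)


def test_zero_variance_rows_excluded_with_warning(rng):
    vals = np.vstack([rng.normal(size=(4, 6)), np.ones((1, 6))])
    with pytest.warns(UserWarning, match="zero-variance"):
        tree = hcluster(_matrix(vals))
    assert tree.n_leaves == 4


# ---------------------------------------------------------------------------
# Node-depth cuts
# ---------------------------------------------------------------------------

def _balanced_tree(n_leaves: int):
    """Perfectly balanced binary tree over 1-D points clustered in pairs."""
    assert (n_leaves & (n_leaves - 1)) == 0
    # points spaced so that sibling distances grow geometrically per level
    coords = []
    for i in range(n_leaves):
        x = 0.0
        for bit in range(int(math.log2(n_leaves))):
            if i >> bit & 1:
                x += 10.0 ** (bit + 1)
        coords.append([x, 0.0])
    m = _matrix(np.asarray(coords))
    return hcluster(m, metric="euclidean")


def test_depth_zero_single_cluster(rng):
    tree = hcluster(_matrix(rng.normal(size=(6, 5))))
    out = cut_by_node_depth(tree, 0)
    assert out.labels.nunique() == 1
    assert set(out.labels.index) == {f"P{i}" for i in range(6)}


def test_balanced_8_leaf_tree_depth_3_gives_singletons():
    tree = _balanced_tree(8)
    out = cut_by_node_depth(tree, 3)
    assert out.labels.nunique() == 8
    assert (out.sizes() == 1).all()


def test_caterpillar_tree_depth_2_gives_3_clusters():
    coords = np.array([[0.0, 0], [1.0, 0], [4.0, 0], [20.0, 0]])
    tree = hcluster(_matrix(coords), metric="euclidean")
    out = cut_by_node_depth(tree, 2)
    assert out.labels.nunique() == 3
    sizes = sorted(out.sizes())
    assert sizes == [1, 1, 2]


def test_oversized_clusters_recut_at_deeper_level():
    tree = _balanced_tree(16)
    out = cut_by_node_depth(tree, 1, subset_threshold=4, subset_depth=3)
    # every depth-1 node has 8 leaves > 4, so both are re-cut at depth 3
    assert out.labels.nunique() == 8
    assert all(d == 3 for d in out.node_depth.values())
    assert (out.sizes() == 2).all()


def test_cut_partitions_and_is_deterministic(rng):
    vals = rng.normal(size=(40, 6))
    tree = hcluster(_matrix(vals))
    a1 = cut_by_node_depth(tree, 3)
    a2 = cut_by_node_depth(hcluster(_matrix(vals)), 3)
    pd.testing.assert_series_equal(a1.labels, a2.labels)
    assert a1.labels.notna().all()


def test_cut_to_n_clusters_reaches_target(rng):
    tree = hcluster(_matrix(rng.normal(size=(30, 6))))
    out = cut_to_n_clusters(tree, 4)
    assert out.labels.nunique() >= 4


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def test_hypergeometric_closed_form():
    universe = {f"g{i}" for i in range(20)}
    term = {f"g{i}" for i in range(5)}
    cluster = set(term)
    out = enrich_terms(cluster, {"T": term}, universe)
    assert out.loc[0, "p"] == pytest.approx(1 / 15504, rel=1e-9)


def test_enrichment_exhaustive_enumeration_oracle(rng):
    # p(overlap >= k) by enumerating all cluster draws on a tiny universe
    from math import comb

    N, K, n = 12, 5, 4
    universe = {f"g{i}" for i in range(N)}
    term = {f"g{i}" for i in range(K)}
    for k in range(0, min(n, K) + 1):
        cluster = set(list(term)[:k]) | {f"g{K + i}" for i in range(n - k)}
        out = enrich_terms(cluster, {"T": term}, universe)
        expected = sum(
            comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1)
        ) / comb(N, n)
        assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-12)


def test_uninformative_and_empty_overlap():
    universe = {f"g{i}" for i in range(10)}
    cluster = {"g0", "g1"}
    out = enrich_terms(cluster, {"ALL": set(universe), "OTHER": {"g8", "g9"}}, universe)
    by_term = out.set_index("term")
    assert by_term.loc["ALL", "p"] == pytest.approx(1.0)
    assert by_term.loc["OTHER", "p"] > 0.5


def test_enrichment_input_validation():
    with pytest.raises(ValidationError):
        enrich_terms({"a"}, {"T": {"a"}}, set())
    with pytest.raises(ValidationError):
        enrich_terms({"zzz"}, {"T": {"a"}}, {"a"})


# ---------------------------------------------------------------------------
# Planted-trajectory recovery
# ---------------------------------------------------------------------------

def test_planted_archetypes_recovered():
    from sklearn.metrics import adjusted_rand_score

    from brewtime.cluster import cut_by_height
    from brewtime.synthetic import SimulationConfig, TrajectoryClass, simulate_timecourse

    cfg = SimulationConfig(
        n_proteins=200,
        trajectory_classes=[
            TrajectoryClass(s, 50, 2.0)
            for s in ("early_peak", "late_rise", "flat_then_drop", "monotone_down")
        ],
        batch_shifts=[],
        complex_plan=[],
        replicate_noise_sd=0.3,
        dropout_rate=0.0,
        seed=9,
    )
    matrix, metadata, truth = simulate_timecourse(cfg)
    rmn = row_mean_normalize(sum_replicates(matrix, metadata))
    tree = hcluster(rmn)
    out = cut_by_height(tree, 4)
    labels_true = [truth.trajectory_class[p] for p in out.labels.index]
    ari = adjusted_rand_score(labels_true, list(out.labels))
    assert ari >= 0.8
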