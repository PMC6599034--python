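from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netdiffuse.graph_distance import (
    DistanceMatrix,
    LabeledGraph,
    cophenetic_correlation,
    hierarchical_cluster,
    labeled_mcs,
    leaf_order,
    mcs_distance,
    pairwise_distances,
    to_newick,
)


def lg(nodes, edges=()):
    return LabeledGraph.build(nodes, edges)


def exhaustive_mcs(g1, g2):
    """Maximal common labeled subgraph by exhaustive search over label subsets.

    For every subset of shared labels, the common (not necessarily induced)
    subgraph with the most edges keeps every edge present in both graphs
    within the subset.  Maximality is by node count, then edge count.
    """
    common = sorted(g1.nodes & g2.nodes)
    best_nodes, best_edges = frozenset(), frozenset()
    for r in range(len(common) + 1):
        for subset in combinations(common, r):
            s = set(subset)
            edges = {
                e for e in g1.edges & g2.edges if e[0] in s and e[1] in s
            }
            if (len(s), len(edges)) > (len(best_nodes), len(best_edges)):
                best_nodes, best_edges = frozenset(s), frozenset(edges)
    return LabeledGraph(nodes=best_nodes, edges=best_edges)


def random_labeled_graph(rng, labels="ABCDEF"):
    n = int(rng.integers(0, len(labels) + 1))
    nodes = list(rng.choice(list(labels), size=n, replace=False))
    edges = [
        (a, b) for a, b in combinations(sorted(nodes), 2) if rng.random() < 0.4
    ]
    return lg(nodes, edges)


class TestLabeledMcs:
    def test_overlapping_paths(self):
        g1 = lg("ABC", [("A", "B"), ("B", "C")])
        g2 = lg("BCD", [("B", "C"), ("C", "D")])
        m = labeled_mcs(g1, g2)
        assert m.nodes == {"B", "C"}
        assert m.edges == {("B", "C")}

    def test_common_subgraph_need_not_be_induced(self):
        g1 = lg("AB", [("A", "B")])
        g2 = lg("AB")  # same labels, no edge
        m = labeled_mcs(g1, g2)
        assert m.nodes == {"A", "B"}
        assert m.edges == frozenset()

    def test_matches_exhaustive_search_on_small_battery(self):
        rng = np.random.default_rng(17)
        graphs = [random_labeled_graph(rng) for _ in range(8)]
        for g1, g2 in combinations(graphs, 2):
            expected = exhaustive_mcs(g1, g2)
            got = labeled_mcs(g1, g2)
            assert got.nodes == expected.nodes
            assert got.edges == expected.edges


class TestMcsDistance:
    def test_formula_examples(self):
        same = lg("ABC", [("A", "B")])
        assert mcs_distance(same, same) == 0.0
        assert mcs_distance(lg("AB", [("A", "B")]), lg("CD", [("C", "D")])) == 1.0
        assert mcs_distance(lg("ABC"), lg("BCD")) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_zero(self):
        assert mcs_distance(lg(""), lg("")) == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        g1, g2 = random_labeled_graph(rng), random_labeled_graph(rng)
        if len(g1) == len(g2) == 0:
            return
        d = mcs_distance(g1, g2)
        assert d == mcs_distance(g2, g1)
        assert 0.0 <= d <= 1.0


class TestPairwiseDistances:
    def test_identical_items_give_zero_matrix(self):
        g = lg("AB", [("A", "B")])
        m = pairwise_distances({"x": g, "y": g})
        np.testing.assert_array_equal(m.values, np.zeros((2, 2)))

    def test_disjoint_items_give_ones_off_diagonal(self):
        m = pairwise_distances({"x": lg("AB"), "y": lg("CD"), "z": lg("EF")})
        assert np.allclose(m.values + np.eye(3), np.ones((3, 3)))

    def test_entries_consistent_with_pairwise_calls(self):
        items = {
            "x": lg("ABC", [("A", "B")]),
            "y": lg("BCD", [("B", "C")]),
            "z": lg("ABD", [("A", "B")]),
        }
        m = pairwise_distances(items)
        for i, a in enumerate(m.names):
            for j, b in enumerate(m.names):
                expected = 0.0 if i == j else mcs_distance(items[a], items[b])
                assert m.values[i, j] == pytest.approx(expected)


def two_block_matrix(names, within=0.1, between=0.9):
    n = len(names)
    half = n // 2
    vals = np.full((n, n), between)
    vals[:half, :half] = within
    vals[half:, half:] = within
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(names=list(names), values=vals)


class TestClustering:
    def test_two_items_merge_at_their_distance(self):
        m = DistanceMatrix(names=["a", "b"], values=[[0, 0.4], [0.4, 0]])
        Z = hierarchical_cluster(m)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.4)

    def test_nearest_pair_merges_first(self):
        vals = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        m = DistanceMatrix(names=["a", "b", "c"], values=vals)
        Z = hierarchical_cluster(m)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_leaf_order_groups_blocks(self):
        m = two_block_matrix(list("abcdef"))
        order = leaf_order(m)
        first_half = set(order[:3])
        assert first_half in ({"a", "b", "c"}, {"d", "e", "f"})

    def test_newick_output_parses_and_covers_leaves(self):
        import dendropy

        m = two_block_matrix(list("abcdef"))
        tree = dendropy.Tree.get(data=to_newick(m), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("abcdef")

    def test_cophenetic_matches_naive_average_linkage(self):
        # independent oracle: naive agglomerative average-linkage clustering
        import scipy.cluster.hierarchy as sch

        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 6
            raw = rng.uniform(0.05, 1.0, size=(n, n))
            vals = (raw + raw.T) / 2
            np.fill_diagonal(vals, 0.0)
            names = [f"i{k}" for k in range(n)]
            m = DistanceMatrix(names=names, values=vals)

            clusters = {i: [i] for i in range(n)}
            heights = np.zeros((n, n))
            active = set(clusters)
            while len(active) > 1:
                best = None
                for a in sorted(active):
                    for b in sorted(active):
                        if a >= b:
                            continue
                        d = np.mean([vals[i, j] for i in clusters[a] for j in clusters[b]])
                        if best is None or d < best[0]:
                            best = (d, a, b)
                d, a, b = best
                for i in clusters[a]:
                    for j in clusters[b]:
                        heights[i, j] = heights[j, i] = d
                clusters[a] = clusters[a] + clusters[b]
                active.discard(b)

            from scipy.spatial.distance import squareform

            expected = squareform(heights, checks=False)
            got = sch.cophenet(hierarchical_cluster(m, "average"))
            np.testing.assert_allclose(got, expected, atol=1e-12)


class TestCopheneticCorrelation:
    def test_self_correlation_is_one(self):
        m = two_block_matrix(list("abcdef"))
        assert cophenetic_correlation(m, m) == pytest.approx(1.0)

    def test_scale_invariance(self):
        m1 = two_block_matrix(list("abcdef"))
        m2 = DistanceMatrix(names=list(m1.names), values=2.5 * m1.values)
        assert cophenetic_correlation(m1, m2) == pytest.approx(1.0)

    def test_reversed_block_structure_decorrelates(self):
        names = list("abcdef")
        m1 = two_block_matrix(names)
        # swap block membership: {a,b,c} vs {d,e,f} becomes {a,e,f} vs {d,b,c}
        perm = [0, 4, 5, 3, 1, 2]
        m2 = DistanceMatrix(names=names, values=m1.values[np.ix_(perm, perm)])
        assert cophenetic_correlation(m1, m2) < 0.5

    def test_name_mismatch_rejected(self):
        m1 = two_block_matrix(list("abcdef"))
        m2 = two_block_matrix(list("uvwxyz"))
        with pytest.raises(ValueError, match="same item names"):
            cophenetic_correlation(m1, m2)

    def test_zero_variance_reported_as_nan(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 0.0)
        m = DistanceMatrix(names=["a", "b", "c"], values=vals)
        assert np.isnan(cophenetic_correlation(m, m))
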