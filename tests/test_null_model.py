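import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netdiffuse.null_model import (
    RandomizationSpec,
    bh_adjust,
    edge_switch_randomize,
    empirical_pvalues,
    extract_subnetwork,
    perturb_network,
    rewired_fraction,
)

from conftest import make_network, random_connected_network, seeds_for


def brute_force_bh(pvals):
    """Step-up definition: q_i = min_{j: p_j >= p_i} m * p_j / rank(p_j), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = np.empty(m)
    running_min = 1.0
    for i in range(m - 1, -1, -1):
        running_min = min(running_min, m * ranked[i] / (i + 1))
        q[i] = running_min
    out = np.empty(m)
    out[order] = q
    return out


class TestEdgeSwitch:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_degree_multiset_preserved(self, seed):
        net = random_connected_network(40, 0.1, seed=seed)
        randomized = edge_switch_randomize(net, 10, rng=seed)
        assert randomized.degree_sequence() == net.degree_sequence()
        assert randomized.nodes == net.nodes

    def test_triangle_has_no_legal_swap(self):
        tri = make_network([("A", "B"), ("B", "C"), ("C", "A")])
        assert edge_switch_randomize(tri, 10, rng=0).edges == tri.edges

    def test_annotations_dropped(self, small_planted_network):
        randomized = edge_switch_randomize(small_planted_network, 5, rng=1)
        assert randomized.pathway_members == {}

    def test_thorough_mixing_replaces_most_edges(self):
        retained = []
        for seed in range(20):
            net = random_connected_network(200, 0.02, seed=seed)
            randomized = edge_switch_randomize(net, 10, rng=1000 + seed)
            retained.append(1 - rewired_fraction(net, randomized))
        assert np.mean(retained) < 0.3


class TestPerturbation:
    def test_identity_fraction_zero(self, small_planted_network):
        assert rewired_fraction(small_planted_network, small_planted_network) == 0.0

    def test_four_cycle_single_swap_fraction(self):
        # one double swap on the 4-cycle replaces 2 of 4 edges
        original = make_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        swapped = make_network([("A", "C"), ("C", "B"), ("B", "D"), ("D", "A")])
        assert swapped.degree_sequence() == original.degree_sequence()
        assert rewired_fraction(original, swapped) == pytest.approx(0.5)

    def test_disjoint_same_degree_graphs_fraction_one(self):
        a = make_network([("A", "B"), ("C", "D")])
        b = make_network([("A", "C"), ("B", "D")])
        assert rewired_fraction(a, b) == 1.0

    def test_node_set_mismatch_rejected(self):
        a = make_network([("A", "B")])
        b = make_network([("A", "C")])
        with pytest.raises(ValueError, match="node sets"):
            rewired_fraction(a, b)

    @pytest.mark.parametrize("target", [0.05, 0.25])
    def test_achieved_fraction_within_one_swap_granularity(self, target):
        net = random_connected_network(60, 0.08, seed=4)
        perturbed = perturb_network(net, target, rng=7)
        achieved = rewired_fraction(net, perturbed)
        assert target <= achieved <= target + 2 / net.n_edges() + 1e-12
        assert perturbed.degree_sequence() == net.degree_sequence()

    def test_annotations_survive_on_kept_edges_only(self, small_planted_network):
        perturbed = perturb_network(small_planted_network, 0.3, rng=2)
        original = small_planted_network.edge_pathways
        for edge, pathways in perturbed.edge_pathways.items():
            if edge in original:
                assert pathways == original[edge]
            else:
                assert pathways == set()


class TestBhAdjust:
    def test_worked_step_up_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.5]) == pytest.approx([0.5])
        assert bh_adjust([0.5, 1.0]) == pytest.approx([1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
    def test_matches_brute_force_step_up(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), brute_force_bh(pvals), atol=1e-12)


class TestEmpiricalPvalues:
    def test_zero_score_node_gets_p_one(self):
        # X, Y unreachable from the seed: every random score >= 0 = f_obs
        net = make_network([("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y"), ("Y", "Z"), ("Z", "X")])
        seeds = seeds_for(net, ["A"])
        table = empirical_pvalues(net, seeds, t=5, spec=RandomizationSpec(n_random=25, rng_seed=0))
        assert table.frame.loc["X", "p"] == 1.0

    def test_pvalue_bounds_and_q_dominates_p(self, small_planted_network):
        seeds = seeds_for(small_planted_network, ["P1G00", "P1G01"])
        table = empirical_pvalues(
            small_planted_network, seeds, t=5, spec=RandomizationSpec(n_random=40, rng_seed=1)
        )
        n = table.n_random
        assert ((table.frame.p >= 1 / (n + 1)) & (table.frame.p <= 1)).all()
        assert (table.frame.q >= table.frame.p - 1e-12).all()

    def test_deterministic_given_seed(self, small_planted_network):
        seeds = seeds_for(small_planted_network, ["P1G00", "P1G01"])
        spec = RandomizationSpec(n_random=30, rng_seed=5)
        a = empirical_pvalues(small_planted_network, seeds, t=5, spec=spec)
        b = empirical_pvalues(small_planted_network, seeds, t=5, spec=spec)
        assert a.frame.equals(b.frame)

    def test_invalid_ensemble_size_rejected(self):
        with pytest.raises(ValueError):
            RandomizationSpec(n_random=0)


class TestExtractSubnetwork:
    def _table(self, net, seeds):
        return empirical_pvalues(net, seeds, t=5, spec=RandomizationSpec(n_random=30, rng_seed=2))

    def test_tiny_alpha_keeps_only_seeds(self, small_planted_network):
        seeds = seeds_for(small_planted_network, ["P1G00", "P1G01"])
        sub = extract_subnetwork(
            small_planted_network, seeds, self._table(small_planted_network, seeds), alpha=1e-9
        )
        assert sub.nodes == seeds.mapped
        assert sub.edges <= small_planted_network.edges

    def test_alpha_one_keeps_everything(self, small_planted_network):
        seeds = seeds_for(small_planted_network, ["P1G00"])
        sub = extract_subnetwork(
            small_planted_network, seeds, self._table(small_planted_network, seeds), alpha=1.0
        )
        assert sub.nodes == small_planted_network.nodes

    def test_edges_are_parent_induced_with_annotations(self, small_planted_network):
        seeds = seeds_for(small_planted_network, ["P1G00", "P1G01"])
        sub = extract_subnetwork(
            small_planted_network, seeds, self._table(small_planted_network, seeds), alpha=0.5
        )
        parent = small_planted_network.edge_pathways
        for edge, pathways in sub.as_network().edge_pathways.items():
            assert edge in parent and pathways == parent[edge]
        for a, b in sub.edges:
            assert a in sub.nodes and b in sub.nodes
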