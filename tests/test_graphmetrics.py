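"""Thresholding, the nine graph metrics, null models, small-worldness, hubs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _bruteforce as bf
from conftest import random_adjacency
from tractnet import graphmetrics as gm


def _weights_from_edges(n, edge_weights):
    w = np.zeros((n, n))
    for (i, j), val in edge_weights.items():
        w[i, j] = w[j, i] = val
    return w


def path_graph(n=3):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return gm.BinaryNetwork(adj)


def star_graph(n=4):
    adj = np.zeros((n, n), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    return gm.BinaryNetwork(adj)


def complete_graph(n):
    return gm.BinaryNetwork(~np.eye(n, dtype=bool))


class TestThresholdGrid:
    def test_study_grid_has_26_levels(self):
        grid = gm.threshold_grid(0.15, 0.40, 0.01)
        assert len(grid) == 26
        assert grid[0] == 0.15 and grid[-1] == 0.40

    def test_generic_grid(self):
        assert np.allclose(gm.threshold_grid(0.1, 0.3, 0.1), [0.1, 0.2, 0.3])


class TestProportionalThreshold:
    def test_keeps_exactly_the_strongest_half(self):
        w = _weights_from_edges(
            4, {(0, 1): 6, (0, 2): 5, (0, 3): 4, (1, 2): 3, (1, 3): 2, (2, 3): 1}
        )
        net = gm.proportional_threshold(w, 0.5)
        assert net.n_edges == 3
        assert net.adjacency[0, 1] and net.adjacency[0, 2] and net.adjacency[0, 3]
        assert not net.adjacency[1, 2]

    def test_level_one_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        w = rng.random((6, 6))
        w = np.triu(w, 1)
        w += w.T
        net = gm.proportional_threshold(w, 1.0)
        assert gm.density(net) == 1.0

    def test_ties_broken_lexicographically(self):
        w = _weights_from_edges(4, {(i, j): 1.0 for i in range(4) for j in range(i + 1, 4)})
        net = gm.proportional_threshold(w, 2 / 6)
        assert net.adjacency[0, 1] and net.adjacency[0, 2]
        assert net.n_edges == 2

    def test_insufficient_nonzero_weights_warns_and_keeps_all(self):
        w = _weights_from_edges(5, {(0, 1): 2.0, (2, 3): 1.0})
        with pytest.warns(UserWarning, match="nonzero"):
            net = gm.proportional_threshold(w, 0.9)
        assert net.n_edges == 2

    def test_density_constant_across_subjects_at_fixed_level(self):
        rng = np.random.default_rng(1)
        densities = set()
        for _ in range(5):
            w = rng.lognormal(3, 0.5, (24, 24))
            w = np.triu(w, 1)
            w += w.T
            densities.add(gm.density(gm.proportional_threshold(w, 0.25)))
        assert len(densities) == 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gm.proportional_threshold(np.zeros((3, 3)), 0.0)
        with pytest.raises(ValueError, match="symmetric"):
            gm.proportional_threshold(np.arange(9.0).reshape(3, 3), 0.5)


class TestMetricExamples:
    def test_complete_graph_values(self):
        net = complete_graph(24)
        assert (gm.degree(net) == 23).all()
        assert gm.density(net) == 1.0
        assert np.allclose(gm.betweenness_centrality(net), 0.0)
        assert np.allclose(gm.characteristic_path_length_nodal(net), 1.0)
        assert gm.global_efficiency(net) == 1.0
        assert np.allclose(gm.local_efficiency(net), 1.0)
        assert np.allclose(gm.clustering_coefficient(net), 1.0)

    def test_empty_graph_values(self):
        net = gm.BinaryNetwork(np.zeros((5, 5), dtype=bool))
        assert (gm.degree(net) == 0).all()
        assert gm.density(net) == 0.0
        assert np.allclose(gm.local_efficiency(net), 0.0)

    def test_path_graph_betweenness_and_efficiency(self):
        net = path_graph(3)
        assert np.allclose(gm.betweenness_centrality(net), [0, 1, 0])
        # pair distances 1, 1, 2 -> mean inverse (1 + 1 + 0.5)/3
        assert gm.global_efficiency(net) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_star_graph_values(self):
        net = star_graph(4)
        assert list(gm.degree(net)) == [3, 1, 1, 1]
        assert gm.density(net) == 0.5
        # centre lies on all C(3,2) leaf pairs
        assert gm.betweenness_centrality(net)[0] == pytest.approx(3.0)
        assert np.allclose(gm.clustering_coefficient(net), 0.0)

    def test_triangle_clustering(self):
        assert np.allclose(gm.clustering_coefficient(complete_graph(3)), 1.0)

    def test_isolated_node_has_zero_local_efficiency_and_path_length(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        net = gm.BinaryNetwork(adj)
        assert gm.local_efficiency(net)[3] == 0.0
        assert gm.characteristic_path_length_nodal(net)[3] == 0.0
        assert gm.reachable_fraction(net)[3] == 0.0

    def test_regular_graph_assortativity_undefined(self):
        ring = gm.ring_lattice_network(10, 2 / 9, rewire_frac=0.0, seed=0)
        assert (gm.degree(ring) == 2).all()
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(gm.assortativity(ring))


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_all_metrics_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        adj = random_adjacency(n, rng.uniform(0.25, 0.8), rng)
        net = gm.BinaryNetwork(adj)
        assert np.array_equal(gm.degree(net), bf.degree(adj))
        assert gm.density(net) == pytest.approx(bf.density(adj))
        assert np.allclose(gm.betweenness_centrality(net), bf.betweenness(adj))
        assert np.allclose(
            gm.characteristic_path_length_nodal(net), bf.path_length_nodal(adj)
        )
        assert gm.global_efficiency(net) == pytest.approx(bf.global_efficiency(adj))
        assert np.allclose(gm.local_efficiency(net), bf.local_efficiency(adj))
        assert np.allclose(gm.clustering_coefficient(net), bf.clustering(adj))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ours, theirs = gm.assortativity(net), bf.assortativity(adj)
        assert (np.isnan(ours) and np.isnan(theirs)) or ours == pytest.approx(theirs)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_metrics_equivariant_under_node_relabelling(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 10))
    adj = random_adjacency(n, 0.5, rng)
    perm = rng.permutation(n)
    adj_p = adj[np.ix_(perm, perm)]
    for metric in (
        gm.degree,
        gm.betweenness_centrality,
        gm.characteristic_path_length_nodal,
        gm.clustering_coefficient,
        gm.local_efficiency,
    ):
        assert np.allclose(metric(adj)[perm], metric(adj_p))
    assert gm.global_efficiency(adj) == pytest.approx(gm.global_efficiency(adj_p))
    assert gm.density(adj) == pytest.approx(gm.density(adj_p))


class TestNullEnsembles:
    def test_nulls_preserve_nodes_edges_and_degree_sequence(self):
        net = gm.ring_lattice_network(24, 0.25, 0.1, seed=3)
        nulls = gm.generate_nulls(net, n_null=100, seed=4)
        deg = net.adjacency.sum(axis=1)
        for t in range(nulls.n_null):
            a = nulls.adjacency[t]
            assert np.array_equal(a, a.T)
            assert not a.diagonal().any()
            assert np.array_equal(a.sum(axis=1), deg)

    def test_nulls_randomize_structure(self):
        net = gm.ring_lattice_network(24, 0.25, 0.05, seed=5)
        nulls = gm.generate_nulls(net, n_null=50, seed=6)
        assert any(
            not np.array_equal(nulls.adjacency[t], net.adjacency) for t in range(50)
        )

    def test_seeded_determinism(self):
        net = gm.ring_lattice_network(24, 0.25, 0.1, seed=7)
        a = gm.generate_nulls(net, n_null=20, seed=8).adjacency
        b = gm.generate_nulls(net, n_null=20, seed=8).adjacency
        assert np.array_equal(a, b)

    def test_star_graph_has_no_valid_swap(self):
        with pytest.warns(UserWarning, match="no valid"):
            nulls = gm.generate_nulls(star_graph(5), n_null=10, seed=0)
        assert nulls.identical_to_source

    def test_too_few_edges_rejected(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        with pytest.raises(ValueError, match=">= 2 edges"):
            gm.generate_nulls(adj, n_null=5)


class TestSmallWorldness:
    def test_sigma_against_self_nulls_is_exactly_one(self):
        net = gm.ring_lattice_network(24, 0.25, 0.1, seed=9)
        stack = np.broadcast_to(net.adjacency, (50,) + net.adjacency.shape).copy()
        nulls = gm.NullEnsemble(stack, net.adjacency, seed=0)
        gamma, lam, sigma = gm.small_worldness(net, nulls)
        assert gamma == 1.0 and lam == 1.0 and sigma == 1.0

    def test_small_world_construction_beats_nulls_on_clustering(self):
        from tractnet._kernels import mean_clustering, null_stats

        net = gm.ring_lattice_network(24, 0.25, 0.1, seed=10)
        nulls = gm.generate_nulls(net, n_null=200, seed=11)
        c_null, _ = null_stats(np.ascontiguousarray(nulls.adjacency))
        assert c_null.mean() < mean_clustering(np.ascontiguousarray(net.adjacency))

    def test_random_graph_sigma_near_one(self):
        rng = np.random.default_rng(12)
        adj = random_adjacency(24, 0.3, rng)
        nulls = gm.generate_nulls(adj, n_null=300, seed=13)
        _g, _l, sigma = gm.small_worldness(adj, nulls)
        assert 0.8 < sigma < 1.25

    def test_kernel_metrics_agree_with_networkx_conventions(self):
        from tractnet._kernels import char_path_length, mean_clustering

        rng = np.random.default_rng(14)
        adj = np.ascontiguousarray(random_adjacency(12, 0.4, rng))
        net = gm.BinaryNetwork(adj)
        assert mean_clustering(adj) == pytest.approx(
            gm.clustering_coefficient(net).mean()
        )
        assert char_path_length(adj) == pytest.approx(bf.char_path_length(adj))


class TestHubDetection:
    def test_homogeneous_network_has_no_hubs(self):
        with pytest.warns(UserWarning, match="zero variance"):
            hubs = gm.detect_hubs(np.full(24, 5.0), np.full(24, 3.0))
        assert hubs.size == 0

    def test_node_high_on_both_metrics_is_the_only_hub(self):
        deg = np.full(24, 10.0)
        bc = np.full(24, 20.0)
        deg[7] = 40.0
        bc[7] = 90.0
        assert list(gm.detect_hubs(deg, bc)) == [7]

    def test_high_degree_alone_is_not_a_hub(self):
        deg = np.full(24, 10.0)
        deg[7] = 40.0
        bc = np.full(24, 20.0)
        bc[3] = 90.0  # betweenness outlier elsewhere
        assert gm.detect_hubs(deg, bc).size == 0


def test_ring_lattice_density_matches_level():
    net = gm.ring_lattice_network(24, 0.25, 0.1, seed=15)
    assert net.n_edges == round(0.25 * 24 * 23 / 2)
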