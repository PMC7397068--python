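import numpy as np
import pytest

from heatnet.diffusion import (
    DeltaSelector,
    DiffusionConfig,
    DiffusionError,
    PPINetwork,
    build_transition_matrix,
    compute_diffusion_kernel,
    exchanged_heat,
    permute_network,
    select_delta,
    threshold_components,
)

from conftest import random_connected_graph


class TestTransitionMatrix:
    def test_two_node_path(self, two_node_net):
        W = build_transition_matrix(two_node_net)
        assert np.array_equal(W, [[0.0, 1.0], [1.0, 0.0]])

    def test_star_splits_center_column(self):
        net = PPINetwork.from_edges([("c", "l1"), ("c", "l2")])
        W = build_transition_matrix(net)
        j = net.index["c"]
        col = W[:, j]
        assert col[net.index["l1"]] == 0.5 and col[net.index["l2"]] == 0.5

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            net = random_connected_graph(rng, int(rng.integers(3, 30)))
            W = build_transition_matrix(net)
            assert np.allclose(W.sum(axis=0), 1.0, atol=1e-12)

    def test_isolated_node_rejected(self):
        g = PPINetwork.from_edges([("a", "b")])
        g.graph.add_node("lonely")
        net = PPINetwork(graph=g.graph, nodes=tuple(sorted(g.graph.nodes)),
                         index={n: i for i, n in enumerate(sorted(g.graph.nodes))})
        with pytest.raises(DiffusionError, match="isolated"):
            build_transition_matrix(net)


class TestDiffusionKernel:
    def test_beta_one_is_identity(self, path_net):
        W = build_transition_matrix(path_net)
        assert np.array_equal(compute_diffusion_kernel(W, 1.0), np.eye(3))

    def test_two_node_closed_form(self, two_node_net):
        W = build_transition_matrix(two_node_net)
        F = compute_diffusion_kernel(W, 0.5)
        expected = np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]])
        assert np.allclose(F, expected, atol=1e-12)

    @pytest.mark.parametrize("beta", [0.0, -0.1, 1.5])
    def test_invalid_beta_rejected(self, beta):
        with pytest.raises(DiffusionError):
            compute_diffusion_kernel(np.eye(2), beta)

    def test_matches_neumann_series(self):
        rng = np.random.default_rng(1)
        net = random_connected_graph(rng, 20)
        W = build_transition_matrix(net)
        beta = 0.4
        F = compute_diffusion_kernel(W, beta)
        series = np.zeros_like(W)
        term = np.eye(W.shape[0])
        for _ in range(200):
            series += term
            term = (1 - beta) * W @ term
        assert np.allclose(F, beta * series, atol=1e-8)

    def test_columns_stochastic_and_nonnegative(self):
        rng = np.random.default_rng(2)
        for beta in (0.2, 0.7):
            net = random_connected_graph(rng, 25)
            F = compute_diffusion_kernel(build_transition_matrix(net), beta)
            assert np.all(F >= 0)
            assert np.allclose(F.sum(axis=0), 1.0, atol=1e-10)


class TestExchangedHeat:
    def test_zero_heat_gives_zero(self, two_node_net):
        F = compute_diffusion_kernel(build_transition_matrix(two_node_net), 0.5)
        assert np.array_equal(exchanged_heat(F, np.zeros(2)), np.zeros((2, 2)))

    def test_two_node_worked_example(self, two_node_net):
        F = compute_diffusion_kernel(build_transition_matrix(two_node_net), 0.5)
        E = exchanged_heat(F, np.array([1.0, 0.0]))
        assert np.allclose(E, [[2 / 3, 0.0], [1 / 3, 0.0]], atol=1e-12)

    def test_column_sums_equal_heat(self):
        rng = np.random.default_rng(3)
        net = random_connected_graph(rng, 15)
        F = compute_diffusion_kernel(build_transition_matrix(net), 0.3)
        h = rng.uniform(0, 2, size=net.n_nodes)
        E = exchanged_heat(F, h)
        assert np.allclose(E.sum(axis=0), h, atol=1e-10)

    def test_negative_heat_rejected(self, two_node_net):
        F = np.eye(2)
        with pytest.raises(DiffusionError, match="nonnegative"):
            exchanged_heat(F, np.array([1.0, -0.1]))


class TestThresholdComponents:
    @pytest.fixture
    def two_node_E(self, two_node_net):
        F = compute_diffusion_kernel(build_transition_matrix(two_node_net), 0.5)
        return exchanged_heat(F, np.array([1.0, 1.0])), two_node_net.nodes

    def test_mutual_exchange_above_delta(self, two_node_E):
        E, nodes = two_node_E
        sub = threshold_components(E, 0.3, 2, nodes)
        assert sub.components == [["a", "b"]]

    def test_delta_above_offdiagonal_gives_empty(self, two_node_E):
        E, nodes = two_node_E
        assert threshold_components(E, 0.4, 2, nodes).components == []

    def test_delta_above_max_gives_empty(self, two_node_E):
        E, nodes = two_node_E
        assert threshold_components(E, E.max() + 1, 2, nodes).components == []

    def test_s_min_filters_small_components(self, two_node_E):
        E, nodes = two_node_E
        assert threshold_components(E, 0.3, 3, nodes).components == []

    def test_nested_under_increasing_delta(self):
        rng = np.random.default_rng(4)
        net = random_connected_graph(rng, 25)
        F = compute_diffusion_kernel(build_transition_matrix(net), 0.4)
        h = rng.uniform(0, 1, size=net.n_nodes)
        E = exchanged_heat(F, h)
        deltas = np.quantile(E[E > 0], [0.5, 0.7, 0.9])
        prev = None
        for d in deltas:
            comps = threshold_components(E, d, 1, net.nodes).components
            if prev is not None:
                for c in comps:
                    assert any(set(c) <= set(pc) for pc in prev)
            prev = comps

    def test_component_ordering_contract(self):
        # two disjoint mutual pairs and one triangle, engineered E
        nodes = ("a", "b", "c", "d", "e", "f", "g")
        E = np.zeros((7, 7))
        for i, j in [(0, 1), (1, 0), (2, 3), (3, 2)]:
            E[i, j] = 1.0
        for i, j in [(4, 5), (5, 6), (6, 4)]:
            E[i, j] = E[j, i] = 1.0
        sub = threshold_components(E, 0.5, 2, nodes)
        assert sub.components == [["e", "f", "g"], ["a", "b"], ["c", "d"]]


class TestPermuteNetwork:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(5)
        net = random_connected_graph(rng, 40)
        for seed in range(10):
            perm = permute_network(net, 10 * net.n_edges, seed)
            assert perm.nodes == net.nodes
            assert np.array_equal(perm.degrees(), net.degrees())
            # still a simple graph with the same edge count
            assert perm.n_edges == net.n_edges

    def test_triangle_has_no_valid_swap(self):
        tri = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        perm = permute_network(tri, 100, seed=0)
        assert perm.edge_set() == tri.edge_set()

    def test_same_seed_same_graph(self):
        rng = np.random.default_rng(6)
        net = random_connected_graph(rng, 30)
        a = permute_network(net, 200, seed=42)
        b = permute_network(net, 200, seed=42)
        assert a.edge_set() == b.edge_set()

    def test_single_edge_returned_unchanged_with_warning(self, two_node_net):
        with pytest.warns(UserWarning, match="fewer than 2 edges"):
            perm = permute_network(two_node_net, 10, seed=0)
        assert perm.edge_set() == two_node_net.edge_set()

    def test_actually_randomises(self):
        rng = np.random.default_rng(7)
        net = random_connected_graph(rng, 40)
        perm = permute_network(net, 10 * net.n_edges, seed=1)
        assert perm.edge_set() != net.edge_set()


class TestSelectDelta:
    def test_vacuous_constraint_returns_zero(self, path_net):
        cfg = DiffusionConfig(l_max=3, n_networks=2, seed=0)
        with pytest.warns(UserWarning, match="vacuous"):
            d = select_delta(path_net, np.array([1.0, 1.0, 1.0]), cfg)
        assert d == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        net = random_connected_graph(rng, 30)
        h = rng.uniform(0, 1, size=net.n_nodes)
        cfg = DiffusionConfig(l_max=5, n_networks=4, seed=9)
        assert select_delta(net, h, cfg) == select_delta(net, h, cfg)

    def test_per_network_minimum_nonincreasing_in_l_max(self):
        # brute-force check of the binary search on a 10-node fixture
        rng = np.random.default_rng(10)
        net = random_connected_graph(rng, 10)
        F = compute_diffusion_kernel(build_transition_matrix(net), 0.4)
        E = exchanged_heat(F, rng.uniform(0, 1, size=net.n_nodes))
        off = np.unique(E[~np.eye(E.shape[0], dtype=bool)])

        def brute(l_max):
            from heatnet.diffusion import _max_scc_size
            for cand in off:
                if _max_scc_size(E, cand) <= l_max:
                    return cand
            return np.nextafter(off[-1], np.inf)

        prev = None
        for l_max in range(2, net.n_nodes):
            d = DeltaSelector._min_delta(E, l_max)
            assert d == pytest.approx(brute(l_max), abs=0)
            if prev is not None:
                assert d <= prev
            prev = d
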