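"""Feature-graph construction and GNN branch oracles: hand-computed
forward passes, TopK pooling vs a brute-force sort, readout statistics."""

import numpy as np
import pytest

from copdfusion.autodiff import Tensor, no_grad
from copdfusion.datatypes import FeatureTable
from copdfusion.gnn import (GNNConfig, PBGraphNet, l2_normalize_rows,
                            topk_pool)
from copdfusion.graph import (FeatureGraph, build_feature_graph,
                              read_edge_list, write_edge_list)


def make_table(values, labels=None):
    values = np.asarray(values, float)
    labels = np.zeros(len(values), int) if labels is None else labels
    names = [f"f{i}" for i in range(values.shape[1])]
    return FeatureTable(values, names, labels)


class TestFeatureGraph:
    def test_duplicated_column_gets_edge(self, rng):
        x = rng.normal(size=(20, 1))
        t = make_table(np.column_stack([x, x, rng.normal(size=(20, 1))]))
        g = build_feature_graph(t)
        assert (0, 1) in g.edges

    def test_negated_column_gets_edge_via_absolute_value(self, rng):
        x = rng.normal(size=(20, 1))
        t = make_table(np.column_stack([x, -x]))
        g = build_feature_graph(t)
        assert g.edges == [(0, 1)]
        assert g.correlation[0] == pytest.approx(-1.0)

    def test_orthogonal_columns_no_edge(self):
        # hand Pearson: r = sum((a-am)(b-bm)) / ... = 0 by construction
        a = np.array([1.0, 1.0, -1.0, -1.0])
        b = np.array([1.0, -1.0, 1.0, -1.0])
        am, bm = a.mean(), b.mean()
        assert np.dot(a - am, b - bm) == 0.0
        g = build_feature_graph(make_table(np.column_stack([a, b])))
        assert g.edges == []

    def test_constant_column_produces_no_edges(self, rng):
        t = make_table(np.column_stack([np.ones(10),
                                        rng.normal(size=(10, 1))]))
        assert build_feature_graph(t).edges == []

    def test_threshold_validation(self, rng):
        t = make_table(rng.normal(size=(10, 3)))
        for bad in (-0.1, 1.0, 2.0):
            with pytest.raises(ValueError):
                build_feature_graph(t, threshold=bad)

    def test_edge_list_roundtrip(self, rng, tmp_path):
        t = make_table(rng.normal(size=(30, 5)))
        g = build_feature_graph(t, threshold=0.0)
        path = tmp_path / "edges.tsv"
        write_edge_list(g, path)
        g2 = read_edge_list(path, g.n_nodes)
        assert g2.edges == g.edges
        assert np.allclose(g2.correlation, g.correlation, atol=1e-6)

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            FeatureGraph(3, [(1, 1)])


def line_graph(n):
    return FeatureGraph(n, [(i, i + 1) for i in range(n - 1)],
                        [1.0] * (n - 1))


class TestGNNLayers:
    def test_init_states_zero_row_zero_bias(self):
        net = PBGraphNet(line_graph(3), GNNConfig(hidden_dim=4, seed=0))
        states = net.init_node_states(np.zeros((2, 3)))
        assert np.allclose(states.data, 0.0)

    def test_init_states_identity_like_embedding(self):
        net = PBGraphNet(line_graph(3), GNNConfig(hidden_dim=1, seed=0))
        net.embed_w.data = np.ones((3, 1))
        net.embed_b.data = np.zeros((3, 1))
        row = np.array([[2.0, -1.0, 0.5]])
        states = net.init_node_states(row)
        assert np.allclose(states.data[0, :, 0], row[0])

    def test_identical_connected_states_aggregate_to_self_and_unit_norm(self):
        graph = FeatureGraph(2, [(0, 1)], [1.0])
        net = PBGraphNet(graph, GNNConfig(hidden_dim=4, n_layers=1, seed=0,
                                          dropout=0.0))
        net.eval()
        h = Tensor(np.tile(np.array([1.0, 2.0, 0.0, -1.0]), (1, 2, 1)))
        with no_grad():
            neigh = (net.agg @ h).data
            out = net.gnn_layers[0](h, net.agg)
        assert np.allclose(neigh, h.data)          # neighbour mean == self
        norms = np.linalg.norm(out.data, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_isolated_node_aggregates_zero(self):
        graph = FeatureGraph(3, [(0, 1)], [1.0])
        agg = graph.mean_aggregation_matrix()
        assert np.allclose(agg[2], 0.0)

    def test_two_node_hand_computed_forward(self):
        """Pencil-and-paper check of one propagation layer (criterion-level
        tolerance 1e-9): concat(self, neighbour mean) -> W -> ReLU -> L2."""
        graph = FeatureGraph(2, [(0, 1)], [1.0])
        net = PBGraphNet(graph, GNNConfig(hidden_dim=2, n_layers=1, seed=0,
                                          dropout=0.0))
        net.eval()
        layer = net.gnn_layers[0]
        w = np.array([[1.0, 0.0],
                      [0.0, 1.0],
                      [1.0, -1.0],
                      [0.5, 0.5]])      # (2*hidden, hidden)
        layer.linear.weight.data = w
        layer.linear.bias.data = np.array([0.1, -0.2])
        h = Tensor(np.array([[[1.0, 2.0], [3.0, -1.0]]]))
        with no_grad():
            out = layer(h, net.agg).data[0]
        # node 0: self (1,2), neigh (3,-1) -> concat @ w + b
        pre0 = np.array([1 + 3 + 0.5 * (-1) + 0.1,
                         2 - 3 + 0.5 * (-1) - 0.2])
        post0 = np.maximum(pre0, 0.0)
        exp0 = post0 / np.linalg.norm(post0)
        # node 1: self (3,-1), neigh (1,2)
        pre1 = np.array([3 + 1 + 0.5 * 2 + 0.1,
                         -1 - 1 + 0.5 * 2 - 0.2])
        post1 = np.maximum(pre1, 0.0)
        exp1 = post1 / np.linalg.norm(post1)
        assert np.allclose(out[0], exp0, atol=1e-9)
        assert np.allclose(out[1], exp1, atol=1e-9)

    def test_unit_norm_rows_property(self, rng):
        net = PBGraphNet(line_graph(6), GNNConfig(hidden_dim=8, seed=1))
        net.eval()
        with no_grad():
            per_layer = net.propagate(
                net.init_node_states(rng.normal(size=(5, 6))))
        for h in per_layer:
            norms = np.linalg.norm(h.data, axis=-1)
            nonzero = norms > 0
            assert np.allclose(norms[nonzero], 1.0, atol=1e-9)


class TestTopKPool:
    def test_basis_projection_returns_first_column(self, rng):
        x = rng.normal(size=(6, 3))
        res = topk_pool(x, np.array([1.0, 0.0, 0.0]), 0.5)
        assert np.allclose(res.scores, x[:, 0])

    def test_scale_invariance_of_projection(self, rng):
        x = rng.normal(size=(7, 4))
        p = rng.normal(size=4)
        r1 = topk_pool(x, p, 0.4)
        r2 = topk_pool(x, 5.0 * p, 0.4)
        assert np.allclose(r1.scores, r2.scores, atol=1e-12)
        assert np.array_equal(r1.selected_indices, r2.selected_indices)

    def test_worked_example(self):
        x = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 3.0], [-1.0, 1.0]])
        p = np.array([1.0, 1.0]) / np.sqrt(2.0)
        res = topk_pool(x, p, 0.5)
        assert np.allclose(res.scores,
                           [0.70710678, 1.41421356, 4.24264069, 0.0])
        assert list(res.selected_indices) == [2, 1]

    def test_zero_projection_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            topk_pool(np.ones((3, 2)), np.zeros(2), 0.5)

    def test_agrees_with_bruteforce_sort(self, rng):
        for _ in range(200):
            n, d = rng.integers(2, 12), rng.integers(1, 5)
            x = rng.normal(size=(n, d))
            p = rng.normal(size=d)
            if np.linalg.norm(p) == 0:
                continue
            ratio = rng.uniform(0.05, 0.99)
            res = topk_pool(x, p, ratio)
            z = x @ p / np.linalg.norm(p)
            m = int(np.ceil(ratio * n))
            order = sorted(range(n), key=lambda i: (-z[i], i))[:m]
            assert list(res.selected_indices) == order
            assert np.allclose(res.scores, z, atol=1e-12)
            assert np.allclose(res.x_pooled,
                               x[order] * np.tanh(z[order])[:, None])


class TestReadoutAndForward:
    def test_readout_mean_equals_max_for_constant_states(self):
        net = PBGraphNet(line_graph(4), GNNConfig(hidden_dim=3, seed=0))
        c = np.array([0.5, -0.25, 1.0])
        states = Tensor(np.tile(c, (2, 4, 1)))
        idx = np.tile(np.arange(4), (2, 1))
        gate = Tensor(np.ones((2, 4, 1)))
        with no_grad():
            s = net.readout([states], idx, gate)
        assert np.allclose(s.data, np.concatenate([c, c])[None, :])

    def test_readout_two_identical_layers_doubles(self, rng):
        net = PBGraphNet(line_graph(4), GNNConfig(hidden_dim=3, seed=0))
        states = Tensor(rng.normal(size=(2, 4, 3)))
        idx = np.tile(np.arange(4), (2, 1))
        gate = Tensor(np.ones((2, 4, 1)))
        with no_grad():
            s1 = net.readout([states], idx, gate)
            s2 = net.readout([states, states], idx, gate)
        assert np.allclose(s2.data, 2.0 * s1.data)

    def test_readout_matches_column_statistics(self, rng):
        net = PBGraphNet(line_graph(3), GNNConfig(hidden_dim=2, seed=0))
        arr = rng.normal(size=(1, 3, 2))
        idx = np.arange(3)[None, :]
        gate = Tensor(np.ones((1, 3, 1)))
        with no_grad():
            s = net.readout([Tensor(arr)], idx, gate)
        expected = np.concatenate([arr[0].mean(0), arr[0].max(0)])
        assert np.allclose(s.data[0], expected, atol=1e-12)

    def test_readout_permutation_invariant(self, rng):
        net = PBGraphNet(line_graph(5), GNNConfig(hidden_dim=3, seed=0))
        arr = rng.normal(size=(1, 5, 3))
        perm = rng.permutation(5)
        idx = np.arange(5)[None, :]
        gate = Tensor(np.ones((1, 5, 1)))
        with no_grad():
            s1 = net.readout([Tensor(arr)], idx, gate)
            s2 = net.readout([Tensor(arr[:, perm])], idx, gate)
        assert np.allclose(s1.data, s2.data, atol=1e-12)

    def test_eval_forward_deterministic(self, rng):
        net = PBGraphNet(line_graph(6), GNNConfig(seed=3))
        net.eval()
        x = rng.normal(size=(4, 6))
        with no_grad():
            z1, l1 = net(x)
            z2, l2 = net(x)
        assert np.array_equal(z1.data, z2.data)
        assert np.array_equal(l1.data, l2.data)
        assert z1.shape == (4, 64) and l1.shape == (4, 2)

    def test_l2_normalize_zero_rows_stay_zero(self):
        x = Tensor(np.array([[0.0, 0.0], [3.0, 4.0]]))
        out = l2_normalize_rows(x)
        assert np.allclose(out.data[0], 0.0)
        assert np.allclose(out.data[1], [0.6, 0.8])
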