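"""Message-passing layers against dense / loop brute-force oracles."""

import numpy as np
import pytest

from kcdta.nn.autograd import Tensor
from kcdta.nn.graph import (GATConv, GCNConv, GINConv, global_max_pool,
                            global_mean_pool)


def random_graph(rng, n_nodes, n_feat, p_edge=0.4):
    feats = rng.normal(size=(n_nodes, n_feat))
    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)
             if rng.random() < p_edge]
    edges = []
    for u, v in pairs:
        edges += [(u, v), (v, u)]
    edge_index = (np.asarray(edges, dtype=np.int64).T if edges
                  else np.zeros((2, 0), dtype=np.int64))
    return feats, edge_index


def dense_gcn_oracle(feats, edge_index, weight, bias):
    """sigma(D^-1/2 (A + I) D^-1/2 H W) evaluated with dense matrices."""
    n = feats.shape[0]
    adj = np.zeros((n, n))
    adj[edge_index[1], edge_index[0]] = 1.0
    adj += np.eye(n)
    dinv = np.diag(1.0 / np.sqrt(adj.sum(axis=1)))
    return np.maximum(dinv @ adj @ dinv @ feats @ weight + bias, 0.0)


def loop_gat_oracle(feats, edge_index, layer):
    """Per-node attention softmax computed with explicit loops (one head)."""
    n = feats.shape[0]
    w = layer.weights[0].data
    a_s, a_d = layer.att_src[0].data, layer.att_dst[0].data
    hw = feats @ w
    out = np.zeros_like(hw)
    neighbors = {i: [i] for i in range(n)}  # self-loop included
    for src, dst in edge_index.T:
        neighbors[int(dst)].append(int(src))
    for i in range(n):
        logits = []
        for j in neighbors[i]:
            e = hw[j] @ a_s + hw[i] @ a_d
            logits.append(e if e > 0 else layer.negative_slope * e)
        logits = np.asarray(logits)
        alpha = np.exp(logits - logits.max())
        alpha /= alpha.sum()
        for a, j in zip(alpha, neighbors[i]):
            out[i] += a * hw[j]
    return out


def loop_gin_oracle(feats, edge_index, layer):
    """(1 + eps) h_v + neighbor sum, through the layer's own MLP."""
    n = feats.shape[0]
    agg = (1.0 + layer.eps.data) * feats.copy()
    for src, dst in edge_index.T:
        agg[dst] += feats[src]
    return layer.mlp(Tensor(agg)).data


class TestGCN:
    def test_single_node_identity_weight_is_input(self, rng):
        layer = GCNConv(3, 3, rng)
        layer.weight.data = np.eye(3)
        layer.bias.data[:] = 0
        x = rng.normal(size=(1, 3))
        out = layer(Tensor(x), np.zeros((2, 0), dtype=np.int64))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_two_nodes_average(self, rng):
        """One edge, identity weight: each row is the mean of both rows."""
        layer = GCNConv(4, 4, rng)
        layer.weight.data = np.eye(4)
        layer.bias.data[:] = 0
        x = rng.normal(size=(2, 4))
        edges = np.array([[0, 1], [1, 0]])
        out = layer(Tensor(x), edges).data
        expected = np.vstack([(x[0] + x[1]) / 2, (x[0] + x[1]) / 2])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_matches_dense_oracle_on_random_graphs(self, rng):
        for _ in range(15):
            n = int(rng.integers(2, 9))
            feats, edges = random_graph(rng, n, 5)
            layer = GCNConv(5, 6, rng)
            got = layer(Tensor(feats), edges).relu().data
            ref = dense_gcn_oracle(feats, edges, layer.weight.data, layer.bias.data)
            np.testing.assert_allclose(got, ref, atol=1e-5)

    def test_shape_error(self, rng):
        with pytest.raises(ValueError, match="shape mismatch"):
            GCNConv(5, 6, rng)(Tensor(np.ones((3, 4))), np.zeros((2, 0), dtype=np.int64))


class TestGAT:
    def test_single_node_self_attention(self, rng):
        """Softmax over one element: output = W x."""
        layer = GATConv(3, 4, rng)
        x = rng.normal(size=(1, 3))
        out = layer(Tensor(x), np.zeros((2, 0), dtype=np.int64)).data
        np.testing.assert_allclose(out, x @ layer.weights[0].data, atol=1e-12)

    def test_identical_nodes_uniform_attention(self, rng):
        layer = GATConv(3, 4, rng)
        row = rng.normal(size=3)
        x = np.vstack([row, row])
        edges = np.array([[0, 1], [1, 0]])
        out = layer(Tensor(x), edges).data
        # identical logits -> alpha = 1/2 each; output = W x for both nodes
        np.testing.assert_allclose(out, x @ layer.weights[0].data, atol=1e-12)

    def test_matches_loop_oracle_on_random_graphs(self, rng):
        for _ in range(15):
            n = int(rng.integers(2, 9))
            feats, edges = random_graph(rng, n, 4)
            layer = GATConv(4, 5, rng)
            got = layer(Tensor(feats), edges).data
            np.testing.assert_allclose(got, loop_gat_oracle(feats, edges, layer),
                                       atol=1e-5)

    def test_attention_rows_sum_to_one(self, rng):
        """Recover each node's attention weights by linearity probes.

        Aggregation is linear in the transformed features once the attention
        weights are fixed, so alpha_ij follows from probing with basis
        vectors substituted for W x_j; each neighborhood's weights must sum
        to one.
        """
        n = 5
        # feature dim >= n keeps the transformed rows linearly independent,
        # so the least-squares solve recovers the unique attention weights
        feats, edges = random_graph(rng, n, 6, p_edge=0.7)
        layer = GATConv(6, 6, rng)
        out = layer(Tensor(feats), edges).data
        hw = feats @ layer.weights[0].data
        # solve out[i] = sum_j alpha_ij hw[j] for alpha via least squares over
        # the neighborhood, then check the simplex constraint
        neighbors = {i: sorted({i} | {int(s) for s, d in edges.T if d == i})
                     for i in range(n)}
        for i in range(n):
            basis = hw[neighbors[i]]
            alpha, *_ = np.linalg.lstsq(basis.T, out[i], rcond=None)
            np.testing.assert_allclose(basis.T @ alpha, out[i], atol=1e-8)
            assert alpha.sum() == pytest.approx(1.0, abs=1e-8)
            assert np.all(alpha > -1e-8)

    def test_multi_head_concatenates(self, rng):
        layer = GATConv(4, 6, rng, heads=2)
        feats, edges = random_graph(rng, 4, 4)
        assert layer(Tensor(feats), edges).shape == (4, 6)

    def test_heads_must_divide(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            GATConv(4, 5, rng, heads=2)


class TestGIN:
    def test_isolated_node_identity_mlp(self, rng):
        layer = GINConv(3, 3, rng)
        layer.mlp = lambda t: t  # identity MLP, eps = 0
        x = rng.normal(size=(1, 3))
        out = layer(Tensor(x), np.zeros((2, 0), dtype=np.int64)).data
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_two_nodes_sum(self, rng):
        layer = GINConv(3, 3, rng)
        layer.mlp = lambda t: t
        x = rng.normal(size=(2, 3))
        edges = np.array([[0, 1], [1, 0]])
        out = layer(Tensor(x), edges).data
        np.testing.assert_allclose(out, np.vstack([x[0] + x[1], x[0] + x[1]]),
                                   atol=1e-12)

    def test_matches_loop_oracle_on_random_graphs(self, rng):
        for _ in range(15):
            n = int(rng.integers(2, 9))
            feats, edges = random_graph(rng, n, 4)
            layer = GINConv(4, 5, rng)
            got = layer(Tensor(feats), edges).data
            np.testing.assert_allclose(got, loop_gin_oracle(feats, edges, layer),
                                       atol=1e-5)

    def test_epsilon_is_learnable_scalar_initialized_zero(self, rng):
        layer = GINConv(3, 3, rng)
        assert layer.eps.data.shape == ()
        assert layer.eps.data == 0.0
        assert layer.eps.requires_grad


class TestGlobalPooling:
    def test_max_and_mean_pool(self, rng):
        x = rng.normal(size=(5, 3))
        batch = np.array([0, 0, 1, 1, 1])
        mx = global_max_pool(Tensor(x), batch, 2).data
        mn = global_mean_pool(Tensor(x), batch, 2).data
        np.testing.assert_allclose(mx[0], x[:2].max(axis=0))
        np.testing.assert_allclose(mx[1], x[2:].max(axis=0))
        np.testing.assert_allclose(mn[0], x[:2].mean(axis=0))
        np.testing.assert_allclose(mn[1], x[2:].mean(axis=0))
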