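"""GVP/GAT layers: equivariance, dense brute-force oracles, readouts."""

import numpy as np
import pytest

from geoprot.autodiff import Tensor
from geoprot.featurizer import ProteinGraph, featurize_graph
from geoprot.layers import (GAT_NEG_SLOPE_DEFAULT, GATLayer, GraphBatch, GVP,
                            GVPConvLayer, gvp_node_norms, readout)
from geoprot.synthetic import ChainSpec, build_chain
from conftest import random_rotation, rigid_transform_structure


def _toy_graph(rng, L=4, k=2, width=6):
    """Hand-buildable random graph with unit-ish features."""
    from geoprot.featurizer import build_knn_edges
    ca = rng.normal(size=(L, 3)) * 6
    src, dst = build_knn_edges(ca, k)
    E = len(src)
    return ProteinGraph(
        n_nodes=L, edge_src=src, edge_dst=dst,
        node_scalar=rng.normal(size=(L, width)),
        node_vector=rng.normal(size=(L, 3, 3)),
        edge_scalar=rng.normal(size=(E, 5)),
        edge_vector=rng.normal(size=(E, 1, 3)),
        feature_mode="onehot")


class TestGVP:
    def test_output_shapes_as_configured(self, rng):
        gvp = GVP((4, 2), (3, 5), np.random.default_rng(0))
        s, V = gvp(Tensor(rng.normal(size=(7, 4))),
                   Tensor(rng.normal(size=(7, 2, 3))))
        assert s.shape == (7, 3) and V.shape == (7, 5, 3)

    def test_zero_vector_channel_gives_zero_vectors(self, rng):
        gvp = GVP((4, 2), (3, 2), np.random.default_rng(0))
        s_in = rng.normal(size=(5, 4))
        s, V = gvp(Tensor(s_in), Tensor(np.zeros((5, 2, 3))))
        assert np.abs(V.data).max() == 0.0
        # scalar path equals the dense transform of (s || ~zero norms)
        norms = np.full((5, gvp.h_dim), np.sqrt(1e-8))
        expected = np.maximum(
            np.concatenate([s_in, norms], axis=1) @ gvp.W_s.weight.data
            + gvp.W_s.bias.data, 0.0)
        np.testing.assert_allclose(s.data, expected, atol=1e-10)

    def test_rotation_equivariance(self, rng):
        gvp = GVP((6, 3), (4, 2), np.random.default_rng(1))
        s_in = Tensor(rng.normal(size=(8, 6)))
        v_in = rng.normal(size=(8, 3, 3))
        s1, V1 = gvp(s_in, Tensor(v_in))
        for _ in range(10):
            R = random_rotation(rng)
            s2, V2 = gvp(s_in, Tensor(v_in @ R.T))
            np.testing.assert_allclose(s2.data, s1.data, rtol=1e-5, atol=1e-12)
            np.testing.assert_allclose(V2.data, V1.data @ R.T, atol=1e-10)

    def test_width_mismatch_raises(self, rng):
        gvp = GVP((4, 2), (3, 2), np.random.default_rng(0))
        with pytest.raises(ValueError):
            gvp(Tensor(rng.normal(size=(5, 7))), Tensor(rng.normal(size=(5, 2, 3))))


def _dense_gvp_conv_oracle(layer, graph, s, V):
    """Loop over every edge explicitly; no vectorized gathers."""
    L = graph.n_nodes
    msgs_s = [[] for _ in range(L)]
    msgs_v = [[] for _ in range(L)]
    for e in range(graph.n_edges):
        j, i = graph.edge_src[e], graph.edge_dst[e]
        ms = np.concatenate([s[j], graph.edge_scalar[e]])[None, :]
        mv = np.concatenate([V[j], graph.edge_vector[e]], axis=0)[None, :]
        ts, tv = Tensor(ms), Tensor(mv)
        for gvp in layer.message_gvps:
            ts, tv = gvp(ts, tv)
        msgs_s[i].append(ts.data[0])
        msgs_v[i].append(tv.data[0])
    out_s = np.zeros_like(s)
    out_v = np.zeros_like(V)
    for i in range(L):
        agg_s = np.mean(msgs_s[i], axis=0) if msgs_s[i] else 0.0
        agg_v = np.mean(msgs_v[i], axis=0) if msgs_v[i] else 0.0
        pre = s[i] + agg_s
        mu, var = pre.mean(), pre.var()
        out_s[i] = ((pre - mu) / np.sqrt(var + 1e-5) * layer.norm.gamma.data
                    + layer.norm.beta.data)
        vsum = V[i] + agg_v
        scale = 1.0 / (np.sqrt((vsum ** 2).sum(-1) + 1e-8).mean() + 1e-6)
        out_v[i] = vsum * scale
    return out_s, out_v


class TestGVPConvLayer:
    def test_matches_dense_loop_oracle(self, rng):
        g = _toy_graph(rng, L=4, k=2, width=6)
        layer = GVPConvLayer((6, 3), (5, 1), np.random.default_rng(3))
        s_out, v_out = layer(g, Tensor(g.node_scalar), Tensor(g.node_vector))
        es, ev = _dense_gvp_conv_oracle(layer, g, g.node_scalar, g.node_vector)
        np.testing.assert_allclose(s_out.data, es, atol=1e-6)
        np.testing.assert_allclose(v_out.data, ev, atol=1e-6)

    def test_zero_messages_reduce_to_normalized_input(self, rng):
        g = _toy_graph(rng, L=5, k=2, width=6)
        layer = GVPConvLayer((6, 3), (5, 1), np.random.default_rng(4))
        # zero all message parameters: messages vanish, residual path remains
        for p in layer.message_gvps[0].parameters():
            p.data = np.zeros_like(p.data)
        s_out, v_out = layer(g, Tensor(g.node_scalar), Tensor(g.node_vector))
        pre = g.node_scalar
        mu = pre.mean(axis=1, keepdims=True)
        var = pre.var(axis=1, keepdims=True)
        np.testing.assert_allclose(
            s_out.data, (pre - mu) / np.sqrt(var + 1e-5), atol=1e-10)
        norms = np.sqrt((g.node_vector ** 2).sum(-1) + 1e-8).mean(1)
        np.testing.assert_allclose(
            v_out.data, g.node_vector / (norms + 1e-6)[:, None, None], atol=1e-10)

    def test_scalar_invariance_after_rigid_transform(self, rng):
        s = build_chain(ChainSpec(length=10, seed=5))
        g = featurize_graph(s, mode="onehot", k=4)
        layer = GVPConvLayer((27, 3), (32, 1), np.random.default_rng(5))
        o1, _ = layer(g, Tensor(g.node_scalar), Tensor(g.node_vector))
        R = random_rotation(rng)
        g2 = featurize_graph(rigid_transform_structure(s, R, rng.normal(size=3)),
                             mode="onehot", k=4)
        o2, _ = layer(g2, Tensor(g2.node_scalar), Tensor(g2.node_vector))
        np.testing.assert_allclose(o2.data, o1.data, rtol=1e-4, atol=1e-10)

    def test_dropout_off_is_deterministic(self, rng):
        g = _toy_graph(rng, L=5, k=2, width=6)
        layer = GVPConvLayer((6, 3), (5, 1), np.random.default_rng(6))
        a = layer(g, Tensor(g.node_scalar), Tensor(g.node_vector))
        b = layer(g, Tensor(g.node_scalar), Tensor(g.node_vector))
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)


def _dense_gat_oracle(layer, graph, h):
    L = graph.n_nodes
    W = layer.W[0].data
    Wh = h @ W
    logits = np.full((L, L), -np.inf)
    for e in range(graph.n_edges):
        j, i = graph.edge_src[e], graph.edge_dst[e]
        logits[i, j] = Wh[i] @ layer.a_dst[0].data + Wh[j] @ layer.a_src[0].data
    for i in range(L):
        logits[i, i] = Wh[i] @ layer.a_dst[0].data + Wh[i] @ layer.a_src[0].data
    finite = np.isfinite(logits)
    logits[finite] = np.where(logits[finite] > 0, logits[finite],
                              GAT_NEG_SLOPE_DEFAULT * logits[finite])
    alpha = np.where(finite, np.exp(logits - logits.max(1, keepdims=True)), 0.0)
    alpha /= alpha.sum(1, keepdims=True)
    return alpha @ Wh


class TestGATLayer:
    def test_matches_dense_oracle(self, rng):
        g = _toy_graph(rng, L=5, k=2, width=6)
        layer = GATLayer(6, 8, np.random.default_rng(7))
        out = layer(g, Tensor(g.node_scalar))
        np.testing.assert_allclose(out.data, _dense_gat_oracle(layer, g,
                                                               g.node_scalar),
                                   atol=1e-6)

    def test_identical_features_give_uniform_attention(self, rng):
        g = _toy_graph(rng, L=6, k=3, width=4)
        h = np.tile(rng.normal(size=(1, 4)), (6, 1))
        layer = GATLayer(4, 4, np.random.default_rng(8))
        out = layer(g, Tensor(h))
        # uniform alpha over the (deg+1)-set sums to 1, so output = W h
        np.testing.assert_allclose(out.data, h @ layer.W[0].data, atol=1e-8)

    def test_isolated_node_keeps_only_self_term(self, rng):
        g = ProteinGraph(
            n_nodes=3, edge_src=np.array([1]), edge_dst=np.array([2]),
            node_scalar=rng.normal(size=(3, 4)),
            node_vector=np.zeros((3, 3, 3)),
            edge_scalar=np.zeros((1, 5)), edge_vector=np.zeros((1, 1, 3)),
            feature_mode="onehot")
        layer = GATLayer(4, 4, np.random.default_rng(9))
        out = layer(g, Tensor(g.node_scalar))
        # node 0 has no in-edges: softmax over {self} alone, alpha_00 = 1
        np.testing.assert_allclose(out.data[0],
                                   g.node_scalar[0] @ layer.W[0].data, atol=1e-10)


class TestReadout:
    def test_sum_pool_additivity_on_duplicated_graph(self, rng):
        feats = rng.normal(size=(6, 5))
        single = readout([Tensor(feats)], pool="sum")
        doubled = readout([Tensor(np.concatenate([feats, feats]))], pool="sum")
        np.testing.assert_allclose(doubled.data, 2 * single.data, atol=1e-12)

    def test_mean_pool_invariant_on_duplicated_graph(self, rng):
        feats = rng.normal(size=(6, 5))
        single = readout([Tensor(feats)], pool="mean")
        doubled = readout([Tensor(np.concatenate([feats, feats]))], pool="mean")
        np.testing.assert_allclose(doubled.data, single.data, atol=1e-12)

    def test_layer_concatenation_width(self, rng):
        outs = [Tensor(rng.normal(size=(7, 100))) for _ in range(3)]
        assert readout(outs, pool="sum").shape == (300,)

    def test_mask_and_empty_mask(self, rng):
        feats = rng.normal(size=(4, 3))
        masked = readout([Tensor(feats)], pool="mean",
                         mask=np.array([True, True, False, False]))
        np.testing.assert_allclose(masked.data, feats[:2].mean(0), atol=1e-12)
        with pytest.raises(ValueError, match="empty mask"):
            readout([Tensor(feats)], pool="mean", mask=np.zeros(4, bool))

    def test_batched_pooling_matches_per_graph(self, rng):
        g1 = featurize_graph(build_chain(ChainSpec(length=8, seed=1)), k=3)
        g2 = featurize_graph(build_chain(ChainSpec(length=11, seed=2)), k=3)
        batch = GraphBatch([g1, g2])
        pooled = readout([Tensor(batch.node_scalar)], pool="mean",
                         node_graph_ids=batch.node_graph_ids, n_graphs=2)
        np.testing.assert_allclose(pooled.data[0], g1.node_scalar.mean(0),
                                   atol=1e-12)
        np.testing.assert_allclose(pooled.data[1], g2.node_scalar.mean(0),
                                   atol=1e-12)


def test_end_to_end_rotation_and_reflection_invariance(rng):
    """featurize -> 3 GVP layers -> mean readout -> head is invariant to
    rigid transforms (and to reflections composed with rotations, since the
    scalar channel sees only norms and invariant scalars)."""
    from geoprot.models import build_model
    from geoprot.autodiff import no_grad
    net = build_model("gvp", "end_to_end", "multilabel", 2, seed=0,
                      hidden_scalar=16, hidden_vector=4)
    s = build_chain(ChainSpec(length=14, seed=10))
    with no_grad():
        base = net.forward([s], [featurize_graph(s, k=6)]).data
    for _ in range(5):
        R = random_rotation(rng)
        t = rng.normal(size=3) * 15
        moved = rigid_transform_structure(s, R, t)
        with no_grad():
            out = net.forward([moved], [featurize_graph(moved, k=6)]).data
        np.testing.assert_allclose(out, base, rtol=1e-4, atol=1e-10)
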