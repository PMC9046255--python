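"""Geometric graph-network layers.

Implements the two message-passing cores used by the structure models:

* the geometric vector perceptron (GVP) — a transform on a tuple
  ``(s, V)`` of per-node scalar features and 3-vector features, built so
  scalar outputs depend on the input only through rotation-invariant
  quantities (vector row norms) while vector outputs transform with the
  input frame;
* a graph attention (GAT) layer on scalar features with softmax attention
  over each node's in-neighbourhood plus itself.

Both layers follow the message-passing scheme: messages are computed per
directed edge from the source node (and, for GVP, the edge features), summed
or averaged over each node's incoming edges, and combined with the previous
state through a residual-plus-normalisation update.

All layers operate on :class:`geoprot.autodiff.Tensor` and are therefore
differentiable end to end.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import (Linear, LayerNorm, Module, Parameter, Tensor, concat,
                       leaky_relu, relu, segment_mean, segment_sum, sigmoid,
                       take_rows, vecmap, vecnorm)
from .featurizer import ProteinGraph


GAT_NEG_SLOPE_DEFAULT = 0.2


class GVP(Module):
    """Geometric vector perceptron: ``(s, V) -> (s', V')``.

    Row-norm formulation: vectors pass through a learned linear map over the
    vector-count axis; their row norms join the scalar channel; the scalar
    output gets a pointwise nonlinearity; the vector output is a second
    linear map gated by a sigmoid of a scalar-derived signal (nonnegative,
    rotation-invariant), so vector equivariance is preserved by construction.
    """

    def __init__(self, in_dims: tuple[int, int], out_dims: tuple[int, int],
                 rng: np.random.Generator, scalar_activation=relu,
                 hidden_vectors: int | None = None):
        s_in, v_in = in_dims
        s_out, v_out = out_dims
        self.in_dims, self.out_dims = (s_in, v_in), (s_out, v_out)
        self.scalar_activation = scalar_activation
        self.h_dim = hidden_vectors or max(v_in, v_out, 1)
        if v_in > 0:
            limit = np.sqrt(6.0 / (v_in + self.h_dim))
            self.W_h = Parameter(rng.uniform(-limit, limit, size=(self.h_dim, v_in)))
            self.W_s = Linear(s_in + self.h_dim, s_out, rng)
        else:
            self.W_h = None
            self.W_s = Linear(s_in, s_out, rng)
        if v_out > 0:
            if v_in == 0:
                raise ValueError("cannot produce vector outputs from scalar-only input")
            limit = np.sqrt(6.0 / (self.h_dim + v_out))
            self.W_mu = Parameter(rng.uniform(-limit, limit, size=(v_out, self.h_dim)))
            self.W_gate = Linear(s_out, v_out, rng)
        else:
            self.W_mu = None
            self.W_gate = None

    def __call__(self, s: Tensor, V: Tensor | None) -> tuple[Tensor, Tensor | None]:
        s_in, v_in = self.in_dims
        if s.shape[-1] != s_in:
            raise ValueError(f"scalar width {s.shape[-1]} != expected {s_in}")
        if v_in > 0:
            if V is None or V.shape[-2] != v_in:
                raise ValueError("vector channel width mismatch")
            Vh = vecmap(V, self.W_h)                     # (n, h_dim, 3)
            norms = vecnorm(Vh, axis=-1)                 # (n, h_dim), invariant
            s_mid = self.W_s(concat([s, norms], axis=-1))
        else:
            s_mid = self.W_s(s)
        s_out = self.scalar_activation(s_mid) if self.scalar_activation else s_mid
        V_out = None
        if self.W_mu is not None:
            Vmu = vecmap(Vh, self.W_mu)                  # (n, v_out, 3)
            gate = sigmoid(self.W_gate(s_mid))           # (n, v_out), invariant
            V_out = ad.mul(Vmu, ad.reshape(gate, gate.shape + (1,)))
        return s_out, V_out


def _vector_layer_scale(V: Tensor) -> Tensor:
    """Per-node normalisation factor for the vector channel: mean row norm.

    A rotation-invariant scalar per node, so dividing by it keeps the
    channel equivariant.
    """
    norms = vecnorm(V, axis=-1)                          # (n, v)
    return ad.pow_(ad.add(ad.mean(norms, axis=-1, keepdims=True), 1e-6), -1.0)


class GVPConvLayer(Module):
    """One GVP graph-convolution step.

    Message ``j -> i`` = GVP stack applied to the concatenation of source
    node features and edge features (scalar channels concatenated, vector
    channels concatenated); aggregation = mean over the incoming messages;
    update = residual + layer normalisation (scalar channel: LayerNorm;
    vector channel: scaled by the reciprocal mean row norm). Dropout acts on
    the aggregated message and only in training mode; vector dropout removes
    whole vector rows so equivariance survives.
    """

    def __init__(self, node_dims: tuple[int, int], edge_dims: tuple[int, int],
                 rng: np.random.Generator, n_message_gvps: int = 1,
                 dropout: float = 0.1):
        self.node_dims, self.edge_dims = node_dims, edge_dims
        self.dropout_rate = dropout
        s_n, v_n = node_dims
        s_e, v_e = edge_dims
        dims_in = (s_n + s_e, v_n + v_e)
        self.message_gvps = []
        for i in range(n_message_gvps):
            last = i == n_message_gvps - 1
            self.message_gvps.append(
                GVP(dims_in, node_dims, rng,
                    scalar_activation=relu if not last else None))
            dims_in = node_dims
        self.norm = LayerNorm(s_n)

    def __call__(self, graph: ProteinGraph | "GraphBatch", s: Tensor, V: Tensor,
                 train_mode: bool = False,
                 rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        L = s.shape[0]
        src, dst = graph.edge_src, graph.edge_dst
        e_s = graph.edge_scalar if isinstance(graph.edge_scalar, Tensor) \
            else Tensor(graph.edge_scalar)
        e_v = graph.edge_vector if isinstance(graph.edge_vector, Tensor) \
            else Tensor(graph.edge_vector)
        m_s = concat([take_rows(s, src), e_s], axis=-1)
        m_v = concat([take_rows(V, src), e_v], axis=1)
        for gvp in self.message_gvps:
            m_s, m_v = gvp(m_s, m_v)
        agg_s = segment_mean(m_s, dst, L)
        agg_v = segment_mean(m_v, dst, L)

        if np.any(np.bincount(dst, minlength=L) == 0):
            import warnings
            warnings.warn("node with zero incoming edges: identity update",
                          stacklevel=2)
        if train_mode and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            agg_s = ad.dropout(agg_s, self.dropout_rate, rng, True)
            keep = (rng.random(agg_v.shape[:2]) >= self.dropout_rate)
            mask = keep[..., None] / (1.0 - self.dropout_rate)
            agg_v = ad.mul(agg_v, mask)

        s_new = self.norm(ad.add(s, agg_s))
        V_sum = ad.add(V, agg_v)
        V_new = ad.mul(V_sum, ad.reshape(_vector_layer_scale(V_sum),
                                         (L, 1, 1)))
        return s_new, V_new


class GATLayer(Module):
    """Graph attention layer on scalar features.

    Attention follows the original GAT recipe: a shared linear map W, a
    pairwise score ``LeakyReLU(a^T [Wh_i || Wh_j])`` and a softmax over each
    node's in-neighbourhood including the node itself; the update is the
    attention-weighted sum of mapped neighbours plus the self term.
    """

    def __init__(self, in_width: int, out_width: int, rng: np.random.Generator,
                 n_heads: int = 1, negative_slope: float = GAT_NEG_SLOPE_DEFAULT):
        if out_width % n_heads:
            raise ValueError("out_width must be divisible by n_heads")
        self.in_width, self.out_width, self.n_heads = in_width, out_width, n_heads
        self.negative_slope = negative_slope
        head_width = out_width // n_heads
        limit = np.sqrt(6.0 / (in_width + head_width))
        self.W = [Parameter(rng.uniform(-limit, limit, size=(in_width, head_width)))
                  for _ in range(n_heads)]
        self.a_dst = [Parameter(rng.uniform(-limit, limit, size=(head_width,)))
                      for _ in range(n_heads)]
        self.a_src = [Parameter(rng.uniform(-limit, limit, size=(head_width,)))
                      for _ in range(n_heads)]

    def __call__(self, graph: ProteinGraph | "GraphBatch", h: Tensor) -> Tensor:
        L = h.shape[0]
        loop = np.arange(L)
        src = np.concatenate([graph.edge_src, loop])
        dst = np.concatenate([graph.edge_dst, loop])
        outs = []
        for W, a_d, a_s in zip(self.W, self.a_dst, self.a_src):
            Wh = ad.matmul(h, W)                                   # (L, d)
            e_dst = ad.matmul(Wh, ad.reshape(a_d, (-1, 1)))        # (L, 1)
            e_src = ad.matmul(Wh, ad.reshape(a_s, (-1, 1)))
            score = leaky_relu(
                ad.add(take_rows(e_dst, dst), take_rows(e_src, src)),
                self.negative_slope)                               # (E+L, 1)
            # segment softmax over each destination's neighbourhood;
            # the per-segment max shift is a constant w.r.t. the softmax value
            shift = np.full(L, -np.inf)
            np.maximum.at(shift, dst, score.data[:, 0])
            ex = ad.exp(ad.add(score, Tensor(-shift[dst][:, None])))
            denom = segment_sum(ex, dst, L)                        # (L, 1)
            alpha = ad.mul(ex, take_rows(ad.pow_(ad.add(denom, 1e-30), -1.0), dst))
            msgs = ad.mul(take_rows(Wh, src), alpha)
            outs.append(segment_sum(msgs, dst, L))
        return outs[0] if len(outs) == 1 else concat(outs, axis=-1)


def readout(layer_outputs: list[Tensor], pool: str = "mean",
            mask: np.ndarray | None = None,
            node_graph_ids: np.ndarray | None = None,
            n_graphs: int = 1) -> Tensor:
    """Concatenate per-node features across layers and pool over nodes.

    ``pool`` is ``"sum"`` or ``"mean"``. ``mask`` (optional boolean per node)
    excludes nodes from the pool; ``node_graph_ids`` pools each graph of a
    batch separately, returning an (n_graphs, width) matrix.
    """
    if not layer_outputs:
        raise ValueError("need at least one layer output")
    if pool not in ("sum", "mean"):
        raise ValueError(f"unknown pool {pool!r}")
    feats = layer_outputs[0] if len(layer_outputs) == 1 \
        else concat(layer_outputs, axis=-1)
    L = feats.shape[0]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask: no valid nodes to pool")
        feats = ad.mul(feats, mask[:, None].astype(float))
    ids = node_graph_ids if node_graph_ids is not None else np.zeros(L, dtype=np.intp)
    if pool == "sum":
        pooled = segment_sum(feats, ids, n_graphs)
    else:
        if mask is None:
            pooled = segment_mean(feats, ids, n_graphs)
        else:
            total = segment_sum(feats, ids, n_graphs)
            counts = np.bincount(ids[mask], minlength=n_graphs).astype(float)
            pooled = ad.mul(total, (1.0 / np.maximum(counts, 1.0))[:, None])
    return pooled if node_graph_ids is not None else ad.reshape(pooled, (pooled.shape[-1],))


def gvp_node_norms(V: Tensor) -> Tensor:
    """Row norms of a vector channel, as invariant scalars for readout."""
    return vecnorm(V, axis=-1)


class GraphBatch:
    """Disjoint union of protein graphs with node-offset bookkeeping."""

    def __init__(self, graphs: list[ProteinGraph]):
        offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
        self.n_graphs = len(graphs)
        self.n_nodes = int(offsets[-1])
        self.node_graph_ids = np.concatenate(
            [np.full(g.n_nodes, i, dtype=np.intp) for i, g in enumerate(graphs)])
        self.edge_src = np.concatenate(
            [g.edge_src + offsets[i] for i, g in enumerate(graphs)])
        self.edge_dst = np.concatenate(
            [g.edge_dst + offsets[i] for i, g in enumerate(graphs)])
        self.node_scalar = np.concatenate([g.node_scalar for g in graphs], axis=0)
        self.node_vector = np.concatenate([g.node_vector for g in graphs], axis=0)
        self.edge_scalar = np.concatenate([g.edge_scalar for g in graphs], axis=0)
        self.edge_vector = np.concatenate([g.edge_vector for g in graphs], axis=0)
        self.feature_mode = graphs[0].feature_mode
        self.offsets = offsets
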