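"""Message-passing layers for molecular graphs.

Three aggregation families over the heavy-atom graph, all consuming a
node-feature matrix ``(N, F)`` and a directed edge index ``(2, E)`` (each
chemical bond present in both directions, no stored self-loops):

* ``GCNConv`` — symmetric-normalized neighborhood averaging,
  ``σ(D̂^{-1/2} Â D̂^{-1/2} H W)`` with ``Â = A + I``.
* ``GATConv`` — attention-weighted aggregation with a single-layer
  LeakyReLU scorer on concatenated transformed features, softmax-normalized
  over each node's first-order neighborhood (self included); multi-head
  outputs are concatenated.
* ``GINConv`` — injective sum aggregation through an MLP,
  ``MLP((1 + ε)·h_v + Σ_{u∈N(v)} h_u)`` with ε a learnable scalar
  initialized at 0.

Layers return pre-activation aggregates; the surrounding stack applies
batch normalization and ReLU.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .layers import Linear, Module, glorot

__all__ = ["GCNConv", "GATConv", "GINConv", "global_max_pool", "global_mean_pool"]


def _with_self_loops(edge_index: np.ndarray, num_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    loops = np.arange(num_nodes, dtype=np.int64)
    src = np.concatenate([edge_index[0], loops])
    dst = np.concatenate([edge_index[1], loops])
    return src, dst


class GCNConv(Module):
    """Graph convolution with renormalized adjacency and self-loops."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(glorot(rng, in_features, out_features,
                                    (in_features, out_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        if x.shape[-1] != self.weight.shape[0]:
            raise ValueError(
                f"shape mismatch: node features have {x.shape[-1]} dims, "
                f"weight expects {self.weight.shape[0]}")
        num_nodes = x.shape[0]
        src, dst = _with_self_loops(edge_index, num_nodes)
        deg_hat = np.bincount(dst, minlength=num_nodes).astype(np.float64)
        norm = 1.0 / np.sqrt(deg_hat[src] * deg_hat[dst])
        hw = x @ self.weight
        messages = hw.rows(src) * norm[:, None]
        return messages.segment_sum(dst, num_nodes) + self.bias


class GATConv(Module):
    """Graph attention; ``heads`` outputs concatenated to ``out_features``."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 heads: int = 1, negative_slope: float = 0.2):
        super().__init__()
        if out_features % heads:
            raise ValueError(f"out_features={out_features} not divisible by heads={heads}")
        self.heads = heads
        self.head_dim = out_features // heads
        self.negative_slope = negative_slope
        self.weights = [
            Tensor(glorot(rng, in_features, self.head_dim, (in_features, self.head_dim)),
                   requires_grad=True)
            for _ in range(heads)
        ]
        # attention vector a, split into source and destination halves
        self.att_src = [
            Tensor(glorot(rng, 2 * self.head_dim, 1, (self.head_dim,)), requires_grad=True)
            for _ in range(heads)
        ]
        self.att_dst = [
            Tensor(glorot(rng, 2 * self.head_dim, 1, (self.head_dim,)), requires_grad=True)
            for _ in range(heads)
        ]

    def __call__(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        num_nodes = x.shape[0]
        src, dst = _with_self_loops(edge_index, num_nodes)
        outputs = []
        for W, a_s, a_d in zip(self.weights, self.att_src, self.att_dst):
            hw = x @ W                                      # (N, D)
            alpha_src = (hw * a_s).sum(axis=1)              # (N,)
            alpha_dst = (hw * a_d).sum(axis=1)
            logits = (alpha_src.rows(src) + alpha_dst.rows(dst)).leaky_relu(
                self.negative_slope)
            # numerically stable softmax over each destination's neighborhood
            shift = np.full(num_nodes, -np.inf)
            np.maximum.at(shift, dst, logits.data)
            z = (logits - shift[dst]).exp()
            denom = z.reshape(-1, 1).segment_sum(dst, num_nodes)  # (N, 1)
            alpha = z * denom.rows(dst).reshape(-1) ** -1.0       # (E,)
            messages = hw.rows(src) * alpha.reshape(-1, 1)
            outputs.append(messages.segment_sum(dst, num_nodes))
        return outputs[0] if len(outputs) == 1 else concat(outputs, axis=1)


class GINConv(Module):
    """Graph isomorphism layer: sum aggregation through a two-layer MLP."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.lin1 = Linear(in_features, out_features, rng)
        self.lin2 = Linear(out_features, out_features, rng)
        self.eps = Tensor(np.zeros(()), requires_grad=True)

    def mlp(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())

    def __call__(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        num_nodes = x.shape[0]
        src, dst = edge_index[0], edge_index[1]
        neighbor_sum = x.rows(src).segment_sum(dst, num_nodes)
        return self.mlp(x * (self.eps + 1.0) + neighbor_sum)


def global_max_pool(x: Tensor, batch_ids: np.ndarray, num_graphs: int) -> Tensor:
    """Per-graph featurewise maximum over node embeddings."""
    return x.segment_max(batch_ids, num_graphs)


def global_mean_pool(x: Tensor, batch_ids: np.ndarray, num_graphs: int) -> Tensor:
    """Per-graph featurewise mean over node embeddings."""
    counts = np.bincount(batch_ids, minlength=num_graphs).astype(np.float64)
    sums = x.segment_sum(batch_ids, num_graphs)
    return sums * (1.0 / np.maximum(counts, 1.0))[:, None]
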