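"""The three-branch affinity network and its configuration.

A molecule branch (stacked GCN/GAT/GIN layers, each followed by batch
normalization and ReLU, then global pooling and a linear projection), an
optional 3D-CNN branch over the 21x21x21 k-mer tensor, and an optional
2D-CNN branch over the 21x21 Cartesian matrix.  The active branch
embeddings are concatenated and passed through a fully connected head
(ReLU + dropout between layers) ending in a single linear output unit —
the predicted affinity on the scale of the training labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .molecule_graph import ATOM_FEATURE_DIM, MoleculeGraph
from .nn.autograd import Tensor, concat
from .nn.graph import GATConv, GCNConv, GINConv, global_max_pool, global_mean_pool
from .nn.layers import BatchNorm1d, Conv2d, Conv3d, Dropout, Linear, MaxPool, Module

__all__ = ["ModelConfig", "KCDTANetwork", "batch_graphs"]

GNN_TYPES = ("gcn", "gat", "gin")
PROTEIN_BRANCHES = ("tensor3d", "matrix2d")


@dataclass
class ModelConfig:
    """Architecture and initialization settings for :class:`KCDTANetwork`.

    ``protein_branches`` selects which protein encodings feed the fusion
    head (both by default; single-branch settings reproduce the 2D-only /
    3D-only ablations).  ``seed`` fixes parameter initialization and
    dropout, so two networks built from equal configs are identical.
    """

    gnn_type: str = "gcn"
    protein_branches: tuple[str, ...] = ("tensor3d", "matrix2d")
    gnn_layers: int = 5
    hidden_dim: int = 128
    embed_dim: int = 128
    fc_dims: tuple[int, ...] = (1024, 512)
    dropout: float = 0.2
    gat_heads: int = 1
    pooling: str = "max"
    seed: int = 0

    def __post_init__(self) -> None:
        self.protein_branches = tuple(self.protein_branches)
        self.fc_dims = tuple(self.fc_dims)
        if self.gnn_type not in GNN_TYPES:
            raise ValueError(f"gnn_type must be one of {GNN_TYPES}, got {self.gnn_type!r}")
        if not self.protein_branches:
            raise ValueError("protein_branches must be non-empty")
        for branch in self.protein_branches:
            if branch not in PROTEIN_BRANCHES:
                raise ValueError(f"unknown protein branch {branch!r}")
        if self.gnn_layers < 1:
            raise ValueError("gnn_layers must be >= 1")
        if min(self.hidden_dim, self.embed_dim, *self.fc_dims) < 1:
            raise ValueError("all dimensions must be positive")
        if self.pooling not in ("max", "mean"):
            raise ValueError(f"pooling must be 'max' or 'mean', got {self.pooling!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def batch_graphs(graphs: list[MoleculeGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate graphs into one disjoint-union graph.

    Returns (node_features, edge_index with offsets applied, per-node graph id).
    """
    if not graphs:
        raise ValueError("empty molecule batch")
    feats = np.concatenate([g.node_features for g in graphs], axis=0)
    edge_chunks, batch_ids = [], []
    offset = 0
    for i, g in enumerate(graphs):
        edge_chunks.append(g.edges + offset)
        batch_ids.append(np.full(g.num_nodes, i, dtype=np.int64))
        offset += g.num_nodes
    edges = np.concatenate(edge_chunks, axis=1)
    return feats, edges, np.concatenate(batch_ids)


class _MoleculeBranch(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        dims = [ATOM_FEATURE_DIM] + [config.hidden_dim] * config.gnn_layers
        self.convs: list[Module] = []
        self.norms: list[Module] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            if config.gnn_type == "gcn":
                conv = GCNConv(d_in, d_out, rng)
            elif config.gnn_type == "gat":
                conv = GATConv(d_in, d_out, rng, heads=config.gat_heads)
            else:
                conv = GINConv(d_in, d_out, rng)
            self.convs.append(conv)
            self.norms.append(BatchNorm1d(d_out))
        self.pooling = config.pooling
        self.project = Linear(config.hidden_dim, config.embed_dim, rng)

    def __call__(self, node_features: np.ndarray, edge_index: np.ndarray,
                 batch_ids: np.ndarray, num_graphs: int) -> Tensor:
        h = Tensor(node_features)
        for conv, norm in zip(self.convs, self.norms):
            h = norm(conv(h, edge_index)).relu()
        if self.pooling == "max":
            pooled = global_max_pool(h, batch_ids, num_graphs)
        else:
            pooled = global_mean_pool(h, batch_ids, num_graphs)
        return self.project(pooled).relu()


class _Protein3dBranch(Module):
    """Three (conv3d -> ReLU -> pool) blocks, widths 8 -> 16 -> 32."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(1, 8, rng)
        self.conv2 = Conv3d(8, 16, rng)
        self.conv3 = Conv3d(16, 32, rng)
        self.pool = MaxPool(3)
        # 21 -> 10 -> 5 -> 2 under same-padding conv + window-2 pooling
        self.project = Linear(32 * 2 * 2 * 2, config.embed_dim, rng)

    def __call__(self, tensors: np.ndarray) -> Tensor:
        if tensors.ndim != 4 or tensors.shape[1:] != (21, 21, 21):
            raise ValueError(f"expected (B, 21, 21, 21) k-mer tensors, got {tensors.shape}")
        x = Tensor(tensors).reshape(tensors.shape[0], 1, 21, 21, 21)
        x = self.pool(self.conv1(x).relu())
        x = self.pool(self.conv2(x).relu())
        x = self.pool(self.conv3(x).relu())
        return self.project(x.reshape(tensors.shape[0], -1)).relu()


class _Protein2dBranch(Module):
    """Three (conv2d -> ReLU -> pool) blocks, widths 16 -> 32 -> 64."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(1, 16, rng)
        self.conv2 = Conv2d(16, 32, rng)
        self.conv3 = Conv2d(32, 64, rng)
        self.pool = MaxPool(2)
        self.project = Linear(64 * 2 * 2, config.embed_dim, rng)

    def __call__(self, matrices: np.ndarray) -> Tensor:
        if matrices.ndim != 3 or matrices.shape[1:] != (21, 21):
            raise ValueError(f"expected (B, 21, 21) pair matrices, got {matrices.shape}")
        x = Tensor(matrices).reshape(matrices.shape[0], 1, 21, 21)
        x = self.pool(self.conv1(x).relu())
        x = self.pool(self.conv2(x).relu())
        x = self.pool(self.conv3(x).relu())
        return self.project(x.reshape(matrices.shape[0], -1)).relu()


class KCDTANetwork(Module):
    """Fused molecule + protein network predicting one affinity per pair."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.molecule_branch = _MoleculeBranch(config, rng)
        self.protein3d = (_Protein3dBranch(config, rng)
                          if "tensor3d" in config.protein_branches else None)
        self.protein2d = (_Protein2dBranch(config, rng)
                          if "matrix2d" in config.protein_branches else None)
        n_branches = 1 + len(config.protein_branches)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        dims = [n_branches * config.embed_dim] + list(config.fc_dims)
        self.fc_layers = [Linear(d_in, d_out, rng) for d_in, d_out in zip(dims[:-1], dims[1:])]
        self.dropouts = [Dropout(config.dropout, self._dropout_rng) for _ in config.fc_dims]
        self.out_layer = Linear(dims[-1], 1, rng)

    def forward(self, graphs: list[MoleculeGraph],
                tensors3d: np.ndarray | None = None,
                matrices2d: np.ndarray | None = None) -> Tensor:
        """Predict affinities; returns a (batch,) tensor."""
        num_graphs = len(graphs)
        if num_graphs == 0:
            raise ValueError("empty molecule batch")
        embeddings = []
        feats, edges, batch_ids = batch_graphs(graphs)
        embeddings.append(self.molecule_branch(feats, edges, batch_ids, num_graphs))
        if self.protein3d is not None:
            if tensors3d is None:
                raise ValueError("model config includes tensor3d branch but no tensors given")
            if tensors3d.shape[0] != num_graphs:
                raise ValueError("molecule and 3D-tensor batch sizes differ")
            embeddings.append(self.protein3d(tensors3d))
        if self.protein2d is not None:
            if matrices2d is None:
                raise ValueError("model config includes matrix2d branch but no matrices given")
            if matrices2d.shape[0] != num_graphs:
                raise ValueError("molecule and 2D-matrix batch sizes differ")
            embeddings.append(self.protein2d(matrices2d))
        x = concat(embeddings, axis=1) if len(embeddings) > 1 else embeddings[0]
        for linear, dropout in zip(self.fc_layers, self.dropouts):
            x = dropout(linear(x).relu())
        return self.out_layer(x).reshape(-1)

    __call__ = forward
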