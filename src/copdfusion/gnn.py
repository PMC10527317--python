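"""The PB branch: mean-aggregation GNN with L2-normalised node states,
TopK graph pooling, multi-scale mean||max readout, and a 64-d feature head.

Per-sample inference on a shared training-set topology: each indicator is a
node whose initial state is that sample's (scalar) indicator value lifted to
``hidden_dim`` by a learned embedding.  Every propagation layer computes

    h_i <- normalize( ReLU( W [h_i || mean_{j in N(i)} h_j] ) )

(the node's own state enters via the concatenation, not the neighbour
mean; isolated nodes aggregate the zero vector).  A single TopK pooling
layer after the last propagation layer scores nodes by the projection
z = X p / ||p|| and keeps the ceil(kN) highest-scoring nodes, gated by
tanh(z) so the projection vector receives gradient.  The readout sums, over
layers, the concatenation of mean- and max-pooled surviving-node states; a
linear layer maps it to the 64-d modality vector z_a and a second linear
layer provides the classification logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, concatenate
from .graph import FeatureGraph
from .layers import Dropout, Linear, Module, ModuleList, xavier_uniform

__all__ = ["GNNConfig", "PoolingResult", "topk_pool", "l2_normalize_rows",
           "PBGraphNet"]


@dataclass(frozen=True)
class GNNConfig:
    n_layers: int = 4
    hidden_dim: int = 32
    dropout: float = 0.05
    pool_ratio: float = 0.5
    out_dim: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 < self.pool_ratio < 1.0:
            raise ValueError("pool_ratio must be in (0, 1)")


@dataclass
class PoolingResult:
    """TopK pooling output: surviving rows (gated), their original ids in
    descending-score order, all node scores, and the projection used."""

    x_pooled: np.ndarray
    selected_indices: np.ndarray
    scores: np.ndarray
    projection: np.ndarray


def _topk_indices(z: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m largest entries, ties broken toward lower index."""
    return np.argsort(-z, axis=-1, kind="stable")[..., :m]


def topk_pool(x: np.ndarray, p: np.ndarray, ratio: float) -> PoolingResult:
    """Reference (non-batched) TopK pooling on plain arrays.

    z = X p / ||p||; the ceil(ratio*N) top-z rows survive and are gated by
    tanh(z).  Score and selection are invariant to positive rescaling of p.
    """
    x = np.asarray(x, float)
    p = np.asarray(p, float)
    norm = np.linalg.norm(p)
    if norm == 0:
        raise ValueError("projection vector must be nonzero")
    m = int(np.ceil(ratio * x.shape[0]))
    if m == 0:
        raise ValueError(f"ratio {ratio} keeps zero of {x.shape[0]} nodes")
    z = x @ p / norm
    idx = _topk_indices(z, m)
    pooled = x[idx] * np.tanh(z[idx])[:, None]
    return PoolingResult(pooled, idx, z, p)


def l2_normalize_rows(x: Tensor, eps: float = 1e-6) -> Tensor:
    """Row-wise L2 normalisation; zero rows stay zero (bounded gradient)."""
    n = np.sqrt((x.data ** 2).sum(axis=-1, keepdims=True))
    safe = np.maximum(n, eps)
    out = x.data / safe

    def back(g):
        dot = (g * out).sum(axis=-1, keepdims=True)
        return ((x, (g - out * dot) / safe),)

    return Tensor._make(out, (x,), back)


class GNNLayer(Module):
    """One propagation layer: concat(self, neighbour-mean) -> linear ->
    ReLU -> dropout -> row L2 normalisation."""

    def __init__(self, hidden_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.linear = Linear(2 * hidden_dim, hidden_dim, rng)
        self.dropout = Dropout(dropout, rng)

    def forward(self, states: Tensor, agg_matrix: Tensor) -> Tensor:
        neigh = agg_matrix @ states
        h = self.linear(concatenate([states, neigh], axis=-1)).relu()
        h = self.dropout(h)
        return l2_normalize_rows(h)


class PBGraphNet(Module):
    """GNN branch producing the 64-d modality vector z_a and class logits."""

    def __init__(self, graph: FeatureGraph, config: GNNConfig = GNNConfig()):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.graph = graph
        self.config = config
        self.agg = Tensor(graph.mean_aggregation_matrix())
        # per-indicator linear lift of the scalar expression value: nodes
        # need identity for per-sample inference on a shared topology
        self.embed_w = Parameter(
            xavier_uniform((graph.n_nodes, config.hidden_dim), rng))
        self.embed_b = Parameter(
            np.zeros((graph.n_nodes, config.hidden_dim)))
        self.gnn_layers = ModuleList(
            GNNLayer(config.hidden_dim, config.dropout, rng)
            for _ in range(config.n_layers)
        )
        self.pool_p = Parameter(xavier_uniform((config.hidden_dim,), rng))
        self.feat = Linear(2 * config.hidden_dim, config.out_dim, rng)
        self.clf = Linear(config.out_dim, 2, rng)

    # --- spec-level sub-operations ------------------------------------------
    def init_node_states(self, sample_rows: np.ndarray | Tensor) -> Tensor:
        """Lift per-node scalars (B, N) to hidden states (B, N, hidden)."""
        x = sample_rows if isinstance(sample_rows, Tensor) else Tensor(
            np.atleast_2d(np.asarray(sample_rows, float)))
        if x.shape[-1] != self.graph.n_nodes:
            raise ValueError(
                f"expected {self.graph.n_nodes} indicator values per sample, "
                f"got {x.shape[-1]}"
            )
        return x.reshape(*x.shape, 1) * self.embed_w + self.embed_b

    def propagate(self, states: Tensor) -> list[Tensor]:
        """Run all layers; returns the per-layer states h^1..h^L."""
        per_layer = []
        h = states
        for layer in self.gnn_layers:
            h = layer(h, self.agg)
            per_layer.append(h)
        return per_layer

    def pool_scores(self, states: Tensor) -> Tensor:
        norm = ((self.pool_p * self.pool_p).sum() + 1e-30).sqrt()
        return (states @ self.pool_p) / norm          # (B, N)

    def readout(self, per_layer: list[Tensor], idx: np.ndarray,
                gate: Tensor) -> Tensor:
        """Sum over layers of mean||max over surviving (gated) nodes."""
        b = idx.shape[0]
        rows = np.arange(b)[:, None]
        s = None
        for h in per_layer:
            sel = h[rows, idx] * gate                  # (B, m, d)
            part = concatenate([sel.mean(axis=1), sel.max(axis=1)], axis=-1)
            s = part if s is None else s + part
        return s                                        # (B, 2*hidden)

    # --- full forward --------------------------------------------------------
    def forward(self, sample_rows) -> tuple[Tensor, Tensor]:
        per_layer = self.propagate(self.init_node_states(sample_rows))
        z = self.pool_scores(per_layer[-1])
        m = int(np.ceil(self.config.pool_ratio * self.graph.n_nodes))
        idx = _topk_indices(z.data, m)
        rows = np.arange(idx.shape[0])[:, None]
        gate = z[rows, idx].tanh().reshape(idx.shape[0], m, 1)
        s = self.readout(per_layer, idx, gate)
        z_a = self.feat(s)
        return z_a, self.clf(z_a)

    def node_scores(self, sample_rows) -> np.ndarray:
        """Eval-mode pooling scores z per indicator, averaged over samples."""
        from .autodiff import no_grad
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                per_layer = self.propagate(self.init_node_states(sample_rows))
                z = self.pool_scores(per_layer[-1])
        finally:
            self.train(was_training)
        return z.data.mean(axis=0)
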