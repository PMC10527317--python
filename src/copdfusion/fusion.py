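"""Low-rank multi-modal fusion (LMF), cross-modal / self-attention
transformer blocks, and the end-to-end fusion head.

LMF computes the tensor-fusion output ``h = W . (z_1 (x) ... (x) z_M)``
without materialising the outer-product tensor: the weight tensor is
parameterised by rank-``r`` per-modality factors ``w_m^{(i)}`` and the
contraction collapses to

    h = prod_m ( sum_{i=1..r} w_m^{(i)} z_m )

(an elementwise product over modalities of modality-projected vectors).
:func:`reconstruct_weight_tensor` + :func:`tensor_fusion_oracle` implement
the dense contraction directly; they serve both as the verification oracle
for the factorised path and as the full tensor-fusion (TFN) baseline.

The fusion head turns each 64-d modality vector into a short token
sequence (attention over a length-1 sequence would be degenerate), runs one
cross-modal transformer block per modality with queries from the modality
and keys/values from the fused vector h, one self-attention block each,
mean-pools tokens, concatenates and classifies with a 2-layer MLP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, concatenate, no_grad
from .layers import LayerNorm, Linear, Module, xavier_uniform

__all__ = [
    "FusionConfig",
    "LMF",
    "lmf_fuse",
    "reconstruct_weight_tensor",
    "tensor_fusion_oracle",
    "scaled_dot_attention",
    "MultiHeadAttention",
    "CrossModalBlock",
    "Tokenizer",
    "FusionHead",
    "MultiModalClassifier",
]


@dataclass(frozen=True)
class FusionConfig:
    d_h: int = 64          # fused-vector dimension (tokenised like z_a, z_v)
    rank: int = 4          # LMF rank r
    n_tokens: int = 8      # tokens per 64-d vector
    d_model: int = 32      # transformer width
    heads: int = 4
    ffn_mult: int = 2
    append_one: bool = False   # optional constant-1 augmentation of z_m
    swap_query: bool = False   # queries from h instead of from the modality
    seed: int = 0

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("LMF rank must be >= 1")
        if self.d_model % self.heads:
            raise ValueError("d_model must be divisible by heads")


# ---------------------------------------------------------------------------
# LMF and its dense oracle
# ---------------------------------------------------------------------------

class LMF(Module):
    """Rank-r factorised tensor fusion of M modality vectors.

    ``factors[m]`` has shape (r, d_h, d_m): slice i is the map w_m^{(i)}.
    """

    def __init__(self, modality_dims: list[int], d_h: int, rank: int,
                 rng: np.random.Generator, append_one: bool = False):
        super().__init__()
        if rank < 1:
            raise ValueError("rank must be >= 1")
        self.d_h, self.rank = d_h, rank
        self.append_one = append_one
        dims = [d + 1 if append_one else d for d in modality_dims]
        self.factors = [
            Parameter(xavier_uniform((rank, d_h, d), rng) / np.sqrt(rank))
            for d in dims
        ]

    def forward(self, z_list: list[Tensor]) -> Tensor:
        if len(z_list) != len(self.factors):
            raise ValueError(
                f"{len(z_list)} modality vectors for {len(self.factors)} factor sets"
            )
        h = None
        for z, fac in zip(z_list, self.factors):
            if not isinstance(z, Tensor):
                z = Tensor(np.atleast_2d(z))
            if self.append_one:
                ones = Tensor(np.ones((*z.shape[:-1], 1), dtype=z.dtype))
                z = concatenate([z, ones], axis=-1)
            r, d_h, d_m = fac.shape
            if z.shape[-1] != d_m:
                raise ValueError(
                    f"modality dim {z.shape[-1]} does not match factor dim {d_m}"
                )
            flat = fac.reshape(r * d_h, d_m).swapaxes(0, 1)   # (d_m, r*d_h)
            proj = (z @ flat).reshape(*z.shape[:-1], r, d_h)
            # elementwise product across modalities per rank slice; the sum
            # over ranks happens only after all modalities are folded in,
            # which is what makes this identical to the dense contraction
            h = proj if h is None else h * proj
        return h.sum(axis=-2)


def lmf_fuse(z_list, factors: list[np.ndarray]) -> np.ndarray:
    """Functional LMF on plain arrays; ``factors[m]`` shaped (r, d_h, d_m).

    h_k = sum_i prod_m <w_{m,k}^{(i)}, z_m> — rank-wise products across
    modalities, summed over ranks, never materialising the outer-product
    tensor.
    """
    h = None
    for z, fac in zip(z_list, factors):
        z = np.asarray(z, float)
        if fac.ndim != 3:
            raise ValueError("each factor set must be (rank, d_h, d_m)")
        if fac.shape[0] < 1:
            raise ValueError("rank must be >= 1")
        if z.shape[-1] != fac.shape[2]:
            raise ValueError(
                f"modality dim {z.shape[-1]} vs factor dim {fac.shape[2]}"
            )
        proj = np.einsum("ikd,...d->...ik", fac, z)
        h = proj if h is None else h * proj
    return h.sum(axis=-2)


def reconstruct_weight_tensor(factors: list[np.ndarray]) -> np.ndarray:
    """Dense weight tensor W of shape (d_h, d_1, ..., d_M):
    W[k] = sum_i outer(w_{1,k}^{(i)}, ..., w_{M,k}^{(i)})."""
    factors = [np.asarray(f, float) for f in factors]
    r, d_h = factors[0].shape[:2]
    out = None
    for i in range(r):
        term = factors[0][i]                       # (d_h, d_1)
        for fac in factors[1:]:
            term = np.einsum("k...,kd->k...d", term, fac[i])
        out = term if out is None else out + term
    return out


def tensor_fusion_oracle(weight: np.ndarray, z_list) -> np.ndarray:
    """h_k = <W[k], z_1 (x) ... (x) z_M> by direct dense contraction."""
    h = np.asarray(weight, float)
    for z in reversed(list(z_list)):
        h = h @ np.asarray(z, float)
    return h


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def scaled_dot_attention(q, k, v):
    """softmax(Q K^T / sqrt(d_k)) V; every output row is a convex
    combination of V's rows.  Accepts arrays or Tensors of shape
    (..., T, d)."""
    q = q if isinstance(q, Tensor) else Tensor(np.asarray(q, float))
    k = k if isinstance(k, Tensor) else Tensor(np.asarray(k, float))
    v = v if isinstance(v, Tensor) else Tensor(np.asarray(v, float))
    d_k = q.shape[-1]
    if d_k == 0:
        raise ValueError("key dimension d_k must be positive")
    if k.shape[-1] != d_k:
        raise ValueError("Q and K must share the key dimension")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("K and V must have the same number of rows")
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    return scores.softmax(axis=-1) @ v


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % heads:
            raise ValueError("d_model must be divisible by heads")
        self.heads = heads
        self.d_head = d_model // heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, query: Tensor, source: Tensor) -> Tensor:
        b, t, d = query.shape
        q = self._split(self.wq(query))
        k = self._split(self.wk(source))
        v = self._split(self.wv(source))
        att = scaled_dot_attention(q, k, v)           # (B, H, T, d_head)
        att = att.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(att)


class CrossModalBlock(Module):
    """Pre-norm transformer block; queries from ``target``, keys/values from
    ``source`` (``source=target`` gives a plain self-attention block)."""

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator,
                 ffn_mult: int = 2):
        super().__init__()
        self.ln_target = LayerNorm(d_model)
        self.ln_source = LayerNorm(d_model)
        self.attn = MultiHeadAttention(d_model, heads, rng)
        self.ln_ffn = LayerNorm(d_model)
        self.ffn_in = Linear(d_model, ffn_mult * d_model, rng)
        self.ffn_out = Linear(ffn_mult * d_model, d_model, rng)

    def forward(self, target: Tensor, source: Tensor | None = None) -> Tensor:
        source = target if source is None else source
        u = target + self.attn(self.ln_target(target), self.ln_source(source))
        return u + self.ffn_out(self.ffn_in(self.ln_ffn(u)).relu())


class Tokenizer(Module):
    """Reshape a d-dim vector into ``n_tokens`` chunks, linearly embed each
    to d_model and add learned positional embeddings."""

    def __init__(self, dim: int, n_tokens: int, d_model: int,
                 rng: np.random.Generator):
        super().__init__()
        if dim % n_tokens:
            raise ValueError(f"vector dim {dim} not divisible by {n_tokens} tokens")
        self.n_tokens = n_tokens
        self.chunk = dim // n_tokens
        self.embed = Linear(self.chunk, d_model, rng)
        self.pos = Parameter(0.02 * rng.standard_normal((n_tokens, d_model)))

    def forward(self, z: Tensor) -> Tensor:
        b = z.shape[0]
        tokens = self.embed(z.reshape(b, self.n_tokens, self.chunk))
        return tokens + self.pos


class FusionHead(Module):
    """LMF -> per-modality cross-modal transformer (against h) -> one
    self-attention layer each -> mean-pool -> concatenate -> 2-layer MLP."""

    def __init__(self, dim_a: int = 64, dim_v: int = 64,
                 config: FusionConfig = FusionConfig()):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        c = config
        self.config = c
        self.lmf = LMF([dim_a, dim_v], c.d_h, c.rank, rng,
                       append_one=c.append_one)
        self.tok_a = Tokenizer(dim_a, c.n_tokens, c.d_model, rng)
        self.tok_v = Tokenizer(dim_v, c.n_tokens, c.d_model, rng)
        self.tok_h = Tokenizer(c.d_h, c.n_tokens, c.d_model, rng)
        self.cross_a = CrossModalBlock(c.d_model, c.heads, rng, c.ffn_mult)
        self.cross_v = CrossModalBlock(c.d_model, c.heads, rng, c.ffn_mult)
        self.self_a = CrossModalBlock(c.d_model, c.heads, rng, c.ffn_mult)
        self.self_v = CrossModalBlock(c.d_model, c.heads, rng, c.ffn_mult)
        self.mlp_in = Linear(2 * c.d_model, c.d_model, rng)
        self.mlp_out = Linear(c.d_model, 2, rng)

    def forward(self, z_a: Tensor, z_v: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (final_vector (B, 2*d_model), logits (B, 2))."""
        h = self.lmf([z_a, z_v])
        ta, tv, th = self.tok_a(z_a), self.tok_v(z_v), self.tok_h(h)
        if self.config.swap_query:
            ua = self.cross_a(th, ta)
            uv = self.cross_v(th, tv)
        else:
            ua = self.cross_a(ta, th)
            uv = self.cross_v(tv, th)
        ua = self.self_a(ua)
        uv = self.self_v(uv)
        final = concatenate([ua.mean(axis=1), uv.mean(axis=1)], axis=-1)
        logits = self.mlp_out(self.mlp_in(final).relu())
        return final, logits


class MultiModalClassifier(Module):
    """End-to-end model: PB graph branch + CT branch + fusion head."""

    def __init__(self, pb_net: Module, ct_net: Module,
                 fusion: FusionHead):
        super().__init__()
        self.pb_net = pb_net
        self.ct_net = ct_net
        self.fusion = fusion

    def forward(self, x_pb, volumes) -> tuple[Tensor, Tensor]:
        z_a, _ = self.pb_net(x_pb)
        z_v, _ = self.ct_net(volumes)
        return self.fusion(z_a, z_v)

    def predict_proba(self, x_pb, volumes) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                _, logits = self.forward(x_pb, volumes)
        finally:
            self.train(was_training)
        return np.exp(Tensor(logits.data).log_softmax(axis=-1).data)
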