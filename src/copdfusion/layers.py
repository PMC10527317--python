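"""Neural-network building blocks on top of :mod:`copdfusion.autodiff`.

Contains the generic layers shared by the graph, convolutional and fusion
models: linear maps, layer/batch normalisation, dropout, and 3-D
convolution / pooling implemented as patch-gather + matrix multiply so that
gradients come for free from the autodiff core.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Linear",
    "LayerNorm",
    "Dropout",
    "Conv3d",
    "BatchNorm3d",
    "MaxPool3d",
    "xavier_uniform",
    "cross_entropy",
]


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax logits (B, C)."""
    labels = np.asarray(labels)
    rows = np.arange(len(labels))
    return -(logits.log_softmax(axis=-1)[rows, labels]).mean()


def xavier_uniform(shape: tuple, rng: np.random.Generator, gain: float = 1.0,
                   dtype=np.float64) -> np.ndarray:
    """Glorot/Xavier uniform initialisation; fan computed on the last two dims."""
    if len(shape) == 1:
        fan_in = fan_out = shape[0]
    else:
        receptive = int(np.prod(shape[:-2])) if len(shape) > 2 else 1
        fan_in, fan_out = shape[-2] * receptive, shape[-1] * receptive
    limit = gain * math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Module:
    def __init__(self):
        self.training = True

    # parameter / submodule discovery by attribute walk, pytorch-style
    def _children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Parameter):
                        yield f"{key}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # checkpointing ----------------------------------------------------------
    #: names of non-trainable state arrays (e.g. batch-norm running stats)
    _buffer_names: tuple[str, ...] = ()

    def named_buffers(self, prefix: str = ""):
        for bname in self._buffer_names:
            yield f"{prefix}{bname}", getattr(self, bname)
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_buffers(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{key}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({k: np.copy(b) for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(own) | set(buffers)) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)
        for k in buffers:
            self._set_buffer(k, np.copy(state[k]))

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            if part.isdigit():
                obj = obj[int(part)]
            else:
                obj = getattr(obj, part)
        setattr(obj, parts[-1], value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float64):
        super().__init__()
        self.weight = Parameter(xavier_uniform((in_dim, out_dim), rng, dtype=dtype))
        self.bias = Parameter(np.zeros(out_dim, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6, dtype=np.float64):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xm = x - mu
        var = (xm * xm).mean(axis=-1, keepdims=True)
        return xm / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; draws masks from an explicitly seeded generator."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
        return x * (keep / (1.0 - self.p))


def _conv_indices(cin: int, in_shape: tuple, kernel: tuple, stride: tuple,
                  padding: tuple) -> tuple[np.ndarray, tuple]:
    """Flat gather indices into a zero-padded (C, D, H, W) volume.

    Returns (idx, out_shape) with idx of shape (L, C*kd*kh*kw), L the number
    of output spatial positions.
    """
    d, h, w = in_shape
    kd, kh, kw = kernel
    sd, sh, sw = stride
    pd, ph, pw = padding
    dp, hp, wp = d + 2 * pd, h + 2 * ph, w + 2 * pw
    od = (dp - kd) // sd + 1
    oh = (hp - kh) // sh + 1
    ow = (wp - kw) // sw + 1
    oz, oy, ox = np.meshgrid(
        np.arange(od) * sd, np.arange(oh) * sh, np.arange(ow) * sw, indexing="ij"
    )
    base = (oz.ravel()[:, None], oy.ravel()[:, None], ox.ravel()[:, None])
    kz, ky, kx = np.meshgrid(np.arange(kd), np.arange(kh), np.arange(kw),
                             indexing="ij")
    z = base[0] + kz.ravel()[None, :]
    y = base[1] + ky.ravel()[None, :]
    x = base[2] + kx.ravel()[None, :]
    spatial = (z * hp + y) * wp + x                       # (L, kd*kh*kw)
    chan = np.arange(cin)[:, None] * (dp * hp * wp)       # (C, 1)
    idx = (spatial[:, None, :] + chan[None, :, :]).reshape(spatial.shape[0], -1)
    return idx.astype(np.intp), (od, oh, ow)


def _windows(xp: np.ndarray, kernel: tuple, stride: tuple) -> np.ndarray:
    """Strided sliding-window view (B, C, od, oh, ow, kd, kh, kw)."""
    sd, sh, sw = stride
    v = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=(2, 3, 4))
    return v[:, :, ::sd, ::sh, ::sw]


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: tuple,
           padding: tuple) -> Tensor:
    """3-D cross-correlation with a hand-written backward pass.

    ``weight`` has shape (C, kd, kh, kw, cout).  The backward pass scatters
    input gradients with one strided slice-add per kernel offset, which is
    orders of magnitude faster than generic index scatter.
    """
    cin, kd, kh, kw, cout = weight.shape
    sd, sh, sw = stride
    pd, ph, pw = padding
    xd = x.data
    if pd or ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    v = _windows(xd, (kd, kh, kw), stride)
    b, _, od, oh, ow = v.shape[:5]
    out = np.tensordot(v, weight.data, axes=([1, 5, 6, 7], [0, 1, 2, 3]))
    out = np.ascontiguousarray(np.moveaxis(out, -1, 1))   # (B, cout, od, oh, ow)

    def back(g):
        gp = np.moveaxis(g, 1, -1)                         # (B, od, oh, ow, cout)
        gw = np.tensordot(v, gp, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
        gc = np.tensordot(gp, weight.data, axes=([4], [4]))
        # gc: (B, od, oh, ow, C, kd, kh, kw) -> scatter into padded input
        gc = np.moveaxis(gc, 4, 1)                         # (B, C, od, oh, ow, k...)
        dxp = np.zeros_like(xd)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    dxp[:, :, i:i + od * sd:sd, j:j + oh * sh:sh,
                        k:k + ow * sw:sw] += gc[..., i, j, k]
        if pd or ph or pw:
            dxp = dxp[:, :, pd:pd + x.shape[2], ph:ph + x.shape[3],
                      pw:pw + x.shape[4]]
        return ((x, dxp), (weight, gw))

    res = Tensor._make(out, (x, weight), back)
    if bias is not None:
        res = res + bias.reshape(1, -1, 1, 1, 1)
    return res


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, kernel: int | tuple,
                 rng: np.random.Generator, stride: int | tuple = 1,
                 padding: int | tuple = 0, bias: bool = True, dtype=np.float32):
        super().__init__()
        as3 = lambda v: (v, v, v) if isinstance(v, int) else tuple(v)
        self.cin, self.cout = cin, cout
        self.kernel, self.stride, self.padding = as3(kernel), as3(stride), as3(padding)
        kd, kh, kw = self.kernel
        self.weight = Parameter(
            xavier_uniform((cin, kd, kh, kw, cout), rng, dtype=dtype)
        )
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class MaxPool3d(Module):
    def __init__(self, kernel: int | tuple, stride: int | tuple | None = None):
        super().__init__()
        as3 = lambda v: (v, v, v) if isinstance(v, int) else tuple(v)
        self.kernel = as3(kernel)
        self.stride = as3(stride) if stride is not None else self.kernel
        self._idx_cache: dict[tuple, tuple] = {}

    def forward(self, x: Tensor) -> Tensor:
        b, c, d, h, w = x.shape
        key = (d, h, w)
        if key not in self._idx_cache:
            self._idx_cache[key] = _conv_indices(
                1, key, self.kernel, self.stride, (0, 0, 0)
            )
        idx, (od, oh, ow) = self._idx_cache[key]
        cols = x.reshape(b * c, -1)[:, idx]               # (B*C, L, k^3)
        return cols.max(axis=-1).reshape(b, c, od, oh, ow)


class GroupNorm3d(Module):
    """Group normalisation over (channel-group, spatial) per sample.

    No running statistics, so train and eval behave identically — much
    more stable than batch statistics at batch size 10.
    """

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        while channels % groups:
            groups //= 2
        self.groups = max(groups, 1)
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        b, c, d, h, w = x.shape
        g = self.groups
        xg = x.reshape(b, g, c // g, d, h, w)
        mu = xg.mean(axis=(2, 3, 4, 5), keepdims=True)
        xm = xg - mu
        var = (xm * xm).mean(axis=(2, 3, 4, 5), keepdims=True)
        norm = (xm / (var + self.eps).sqrt()).reshape(b, c, d, h, w)
        shape = (1, -1, 1, 1, 1)
        return norm * self.gamma.reshape(shape) + self.beta.reshape(shape)


class BatchNorm3d(Module):
    """Channel batch normalisation with running statistics for eval mode."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            xm = x - mu
            var = (xm * xm).mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            norm = xm / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
            norm = (x - mu) / sd
        return norm * self.gamma.reshape(shape) + self.beta.reshape(shape)
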