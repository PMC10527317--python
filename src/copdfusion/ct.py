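"""The CT branch: HU normalisation, augmentation, crop/resize, and 3-D
residual CNNs producing the modality vector z_v.

Two backbones share one interface: ``resnet50_3d`` (the full bottleneck
network; stem + 3/4/6/3 stages) and ``resnet_lite_3d`` (a 3-stage basic-block
network, ~70k parameters) sized for desk-scale volumes so the full pipeline
trains in seconds on one CPU.  An injectable ``mask_hook`` stands in for
lung-parenchyma segmentation (identity by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .autodiff import Tensor, no_grad
from .datatypes import CTVolume, NormalizedVolume
from .layers import (BatchNorm3d, Conv3d, Linear, MaxPool3d, Module,
                     ModuleList, cross_entropy)
from .optim import Adam, StepLR

__all__ = [
    "CNNConfig",
    "lite_config",
    "hu_normalize",
    "hu_window_from_volumes",
    "augment_rotate",
    "crop_resize",
    "build_backbone",
    "cnn_forward",
    "pretrain_cnn",
    "refresh_norm_stats",
]


@dataclass(frozen=True)
class CNNConfig:
    backbone: str = "resnet50_3d"
    input_shape: tuple = (30, 224, 224)
    out_dim: int = 64
    lr: float = 2e-5
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 1e-3
    lr_step: int = 10
    lr_gamma: float = 0.1
    batch_size: int = 10
    epochs: int = 20
    hu_window: tuple | None = (-1000.0, 400.0)
    crop_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in ("resnet50_3d", "resnet_lite_3d"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


def lite_config(input_shape: tuple = (16, 32, 32), epochs: int = 10,
                lr: float = 1e-3, **overrides) -> CNNConfig:
    """Desk-scale preset: small backbone trained from scratch, so a larger
    learning rate than the pretrained-ResNet50 recipe."""
    return CNNConfig(backbone="resnet_lite_3d", input_shape=input_shape,
                     epochs=epochs, lr=lr, **overrides)


# ---------------------------------------------------------------------------
# preprocessing ops
# ---------------------------------------------------------------------------

def hu_normalize(volume: CTVolume | np.ndarray, hu_min: float,
                 hu_max: float) -> NormalizedVolume:
    """Linear HU -> [0, 1] mapping, I = (H - hu_min)/(hu_max - hu_min),
    clipped to [0, 1]."""
    if hu_max <= hu_min:
        raise ValueError(f"hu_max ({hu_max}) must exceed hu_min ({hu_min})")
    if isinstance(volume, CTVolume):
        vox, sid = volume.voxels, volume.sample_id
    else:
        vox, sid = np.asarray(volume, np.float32), ""
    out = np.clip((vox - hu_min) / (hu_max - hu_min), 0.0, 1.0)
    return NormalizedVolume(out.astype(np.float32), float(hu_min),
                            float(hu_max), sid)


def hu_window_from_volumes(volumes: Sequence[CTVolume]) -> tuple[float, float]:
    """Dataset-level (min, max) HU over the given (training) volumes."""
    lo = min(float(v.voxels.min()) for v in volumes)
    hi = max(float(v.voxels.max()) for v in volumes)
    return lo, hi


def augment_rotate(voxels: np.ndarray, rng: np.random.Generator,
                   max_deg: float = 15.0, order: int = 1,
                   background: float | None = None) -> np.ndarray:
    """In-plane rotation about the z axis by theta ~ U(-max_deg, +max_deg),
    identical for every slice; shape preserved.  Out-of-frame voxels are
    filled with ``background`` — by default the volume's median intensity,
    i.e. the parenchyma level, so rotation corners do not masquerade as
    low-attenuation tissue."""
    theta = float(rng.uniform(-max_deg, max_deg))
    if background is None:
        background = float(np.median(voxels))
    return rotate_volume(voxels, theta, order=order, background=background)


def rotate_volume(voxels: np.ndarray, theta_deg: float, order: int = 1,
                  background: float = 0.0) -> np.ndarray:
    if theta_deg == 0.0:
        return np.asarray(voxels).copy()
    return ndimage.rotate(np.asarray(voxels), theta_deg, axes=(1, 2),
                          reshape=False, order=order, cval=background,
                          prefilter=False)


def crop_resize(voxels: np.ndarray, target_shape: tuple = (30, 224, 224),
                crop_fraction: float = 1.0) -> np.ndarray:
    """Centre-crop each axis to ``crop_fraction`` then trilinearly resample
    to ``target_shape`` (depth included, standardising slice count)."""
    v = np.asarray(voxels)
    if v.size == 0:
        raise ValueError("empty volume")
    if not 0.0 < crop_fraction <= 1.0:
        raise ValueError("crop_fraction must be in (0, 1]")
    if crop_fraction < 1.0:
        sl = []
        for s in v.shape:
            keep = max(1, int(round(s * crop_fraction)))
            lo = (s - keep) // 2
            sl.append(slice(lo, lo + keep))
        v = v[tuple(sl)]
    if v.shape == tuple(target_shape):
        return v.astype(np.float32, copy=True)
    zoom = [t / s for t, s in zip(target_shape, v.shape)]
    out = ndimage.zoom(v.astype(np.float64), zoom, order=1, grid_mode=True,
                       mode="nearest")
    # zoom can be off by one voxel on some ratios; pad/trim defensively
    out = out[tuple(slice(0, t) for t in target_shape)]
    pads = [(0, t - s) for t, s in zip(target_shape, out.shape)]
    if any(p[1] for p in pads):
        out = np.pad(out, pads, mode="edge")
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

class BasicBlock3d(Module):
    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, 3, rng, stride=stride, padding=1,
                            bias=False)
        self.bn1 = BatchNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, 3, rng, stride=1, padding=1,
                            bias=False)
        self.bn2 = BatchNorm3d(cout)
        if stride != 1 or cin != cout:
            self.proj = Conv3d(cin, cout, 1, rng, stride=stride, bias=False)
            self.bn_proj = BatchNorm3d(cout)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        skip = x if self.proj is None else self.bn_proj(self.proj(x))
        return (out + skip).relu()


class Bottleneck3d(Module):
    def __init__(self, cin: int, mid: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        cout = 4 * mid
        self.conv1 = Conv3d(cin, mid, 1, rng, bias=False)
        self.bn1 = BatchNorm3d(mid)
        self.conv2 = Conv3d(mid, mid, 3, rng, stride=stride, padding=1,
                            bias=False)
        self.bn2 = BatchNorm3d(mid)
        self.conv3 = Conv3d(mid, cout, 1, rng, bias=False)
        self.bn3 = BatchNorm3d(cout)
        if stride != 1 or cin != cout:
            self.proj = Conv3d(cin, cout, 1, rng, stride=stride, bias=False)
            self.bn_proj = BatchNorm3d(cout)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        skip = x if self.proj is None else self.bn_proj(self.proj(x))
        return (out + skip).relu()


class _CNNBase(Module):
    def forward(self, x) -> tuple[Tensor, Tensor]:
        """x: (B, D, H, W) or (B, 1, D, H, W) normalised voxels."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, np.float32))
        if x.ndim == 4:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        h = self.features(x)
        h = h.mean(axis=(2, 3, 4))          # global average pool -> (B, C)
        z_v = self.feat(h)
        return z_v, self.clf(z_v)


class ResNetLite3D(_CNNBase):
    """3-stage basic-block residual network for desk-scale volumes."""

    def __init__(self, out_dim: int = 64, seed: int = 0,
                 channels: tuple = (8, 16, 32)):
        super().__init__()
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.stem = Conv3d(1, c1, 3, rng, stride=2, padding=1, bias=False)
        self.bn_stem = BatchNorm3d(c1)
        self.blocks = ModuleList([
            BasicBlock3d(c1, c2, 2, rng),
            BasicBlock3d(c2, c3, 2, rng),
        ])
        self.feat = Linear(c3, out_dim, rng, dtype=np.float32)
        self.clf = Linear(out_dim, 2, rng, dtype=np.float32)

    def features(self, x: Tensor) -> Tensor:
        h = self.bn_stem(self.stem(x)).relu()
        for block in self.blocks:
            h = block(h)
        return h


class ResNet50_3D(_CNNBase):
    """ResNet50 with 3-D kernels; a trailing linear layer matches the
    modality feature dimension."""

    def __init__(self, out_dim: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.stem = Conv3d(1, 64, 7, rng, stride=2, padding=3, bias=False)
        self.bn_stem = BatchNorm3d(64)
        self.pool = MaxPool3d(3, stride=2)
        blocks = []
        cin = 64
        for stage, (mid, n, stride) in enumerate(
                [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)]):
            for b in range(n):
                blocks.append(Bottleneck3d(cin, mid, stride if b == 0 else 1,
                                           rng))
                cin = 4 * mid
        self.blocks = ModuleList(blocks)
        self.feat = Linear(2048, out_dim, rng, dtype=np.float32)
        self.clf = Linear(out_dim, 2, rng, dtype=np.float32)

    def features(self, x: Tensor) -> Tensor:
        h = self.bn_stem(self.stem(x)).relu()
        if min(h.shape[2:]) >= 3:
            h = self.pool(h)
        for block in self.blocks:
            h = block(h)
        return h


def build_backbone(config: CNNConfig) -> _CNNBase:
    if config.backbone == "resnet_lite_3d":
        return ResNetLite3D(out_dim=config.out_dim, seed=config.seed)
    return ResNet50_3D(out_dim=config.out_dim, seed=config.seed)


def cnn_forward(model: _CNNBase, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode forward of a (B, D, H, W) normalised batch -> (z_v, logits)."""
    was_training = model.training
    model.eval()
    try:
        with no_grad():
            z_v, logits = model(batch)
    finally:
        model.train(was_training)
    return z_v.data, logits.data


# ---------------------------------------------------------------------------
# image-only pretraining
# ---------------------------------------------------------------------------

def prepare_volumes(volumes: Sequence[CTVolume], config: CNNConfig,
                    hu_window: tuple | None = None,
                    mask_hook: Callable[[np.ndarray], np.ndarray] | None = None,
                    ) -> np.ndarray:
    """mask -> HU-normalise -> crop/resize; returns a (n, D, H, W) stack."""
    if hu_window is None:
        hu_window = config.hu_window or hu_window_from_volumes(volumes)
    lo, hi = hu_window
    out = np.empty((len(volumes), *config.input_shape), np.float32)
    for i, vol in enumerate(volumes):
        vox = vol.voxels if mask_hook is None else mask_hook(vol.voxels)
        norm = hu_normalize(vox, lo, hi).voxels
        out[i] = crop_resize(norm, config.input_shape, config.crop_fraction)
    return out


def refresh_norm_stats(model: _CNNBase, x: np.ndarray, batch_size: int = 10,
                       limit: int = 80) -> None:
    """Recalibrate batch-norm running statistics on un-augmented data.

    Training batches are rotated/flipped, so the running statistics drift
    away from the clean distribution the model sees at evaluation; a few
    forward passes over clean volumes realign them.
    """
    model.train()
    with no_grad():
        for start in range(0, min(len(x), limit), batch_size):
            model(x[start:start + batch_size])


def pretrain_cnn(x: np.ndarray, labels: np.ndarray, config: CNNConfig,
                 model: _CNNBase | None = None, augment: bool = True,
                 x_val: np.ndarray | None = None,
                 y_val: np.ndarray | None = None,
                 ) -> tuple[_CNNBase, list[float]]:
    """Train the CNN on the image-only task; returns (model, epoch losses).

    ``x`` is a prepared (n, D, H, W) stack in [0, 1].  Augmentation (random
    z-axis rotation plus random in-plane flips, both label-preserving for
    texture statistics) is applied to training copies only; the flips keep
    the small network from memorising small noisy-label cohorts.  With a
    validation set the best-validation-accuracy epoch weights are kept.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("pretraining needs both classes present")
    model = model if model is not None else build_backbone(config)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr, betas=config.betas,
               eps=config.eps, weight_decay=config.weight_decay)
    sched = StepLR(opt, config.lr_step, config.lr_gamma)
    n = len(labels)
    history: list[float] = []
    best: tuple[float, dict] | None = None
    model.train()
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = x[idx]
            if augment:
                batch = np.stack([
                    augment_rotate(v, rng) for v in batch
                ]).astype(np.float32)
                fl = rng.random(len(idx)) < 0.5
                batch[fl] = batch[fl, :, :, ::-1]
                fl = rng.random(len(idx)) < 0.5
                batch[fl] = batch[fl, :, ::-1, :]
            _, logits = model(batch)
            loss = cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        sched.step()
        history.append(total / n)
        if augment:
            refresh_norm_stats(model, x)
        if x_val is not None:
            _, vlogits = cnn_forward(model, x_val)
            acc = float((vlogits.argmax(axis=1) == y_val).mean())
            if best is None or acc >= best[0]:
                best = (acc, model.state_dict())
    if best is not None:
        model.load_state_dict(best[1])
        if augment:
            refresh_norm_stats(model, x)
    return model, history
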