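"""Run configuration: YAML file -> validated, fully-resolved config.

Unknown keys are rejected (typos fail loudly); every CLI run writes the
resolved configuration next to its outputs so any artifact can be
reproduced from (config, seed, package version).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .ct import CNNConfig
from .fusion import FusionConfig
from .gnn import GNNConfig
from .synthetic import SyntheticSpec
from .train import SplitSpec, TrainSpec


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Section):
    n_samples: int = 300
    n_features: int = 24
    correlated_blocks: list = Field(default_factory=lambda: [
        [[13, 14, 15], 0.6], [[7, 8, 11], 0.5]])
    informative_features: list = Field(default_factory=lambda: [
        [6, 1.5], [3, 1.5], [12, 1.5], [22, 1.5]])
    outlier_fraction: float = 0.0167
    repeated_meas_rate: float = 0.03
    volume_shape: list[int] = Field(default_factory=lambda: [16, 32, 32])
    volume_effect: float = 1.0
    modality_signal: str = "complementary"
    label_balance: float = 0.5

    def to_spec(self, seed: int) -> SyntheticSpec:
        return SyntheticSpec(
            n_samples=self.n_samples, n_features=self.n_features,
            correlated_blocks=tuple((tuple(b[0]), b[1])
                                    for b in self.correlated_blocks),
            informative_features=tuple((int(j), float(d))
                                       for j, d in self.informative_features),
            outlier_fraction=self.outlier_fraction,
            repeated_meas_rate=self.repeated_meas_rate,
            volume_shape=tuple(self.volume_shape),
            volume_effect=self.volume_effect,
            modality_signal=self.modality_signal,
            label_balance=self.label_balance, seed=seed,
        )


class PreprocessSection(_Section):
    knn_k: int = 10
    target_time: float = 3.0


class GNNSection(_Section):
    n_layers: int = 4
    hidden_dim: int = 32
    dropout: float = 0.05
    pool_ratio: float = 0.5
    out_dim: int = 64
    graph_threshold: float = 0.3

    def to_config(self, seed: int) -> GNNConfig:
        return GNNConfig(n_layers=self.n_layers, hidden_dim=self.hidden_dim,
                         dropout=self.dropout, pool_ratio=self.pool_ratio,
                         out_dim=self.out_dim, seed=seed)


class CNNSection(_Section):
    backbone: str = "resnet_lite_3d"
    input_shape: list[int] = Field(default_factory=lambda: [16, 32, 32])
    out_dim: int = 64
    lr: float = 1e-3
    weight_decay: float = 1e-3
    lr_step: int = 10
    lr_gamma: float = 0.1
    batch_size: int = 10
    epochs: int = 25
    hu_window: Optional[list[float]] = Field(
        default_factory=lambda: [-1000.0, 400.0])
    crop_fraction: float = 1.0

    def to_config(self, seed: int) -> CNNConfig:
        return CNNConfig(
            backbone=self.backbone, input_shape=tuple(self.input_shape),
            out_dim=self.out_dim, lr=self.lr,
            weight_decay=self.weight_decay, lr_step=self.lr_step,
            lr_gamma=self.lr_gamma, batch_size=self.batch_size,
            epochs=self.epochs,
            hu_window=None if self.hu_window is None else tuple(self.hu_window),
            crop_fraction=self.crop_fraction, seed=seed,
        )


class FusionSection(_Section):
    d_h: int = 64
    rank: int = 4
    n_tokens: int = 8
    d_model: int = 32
    heads: int = 4
    append_one: bool = False
    swap_query: bool = False

    def to_config(self, seed: int) -> FusionConfig:
        return FusionConfig(d_h=self.d_h, rank=self.rank,
                            n_tokens=self.n_tokens, d_model=self.d_model,
                            heads=self.heads, append_one=self.append_one,
                            swap_query=self.swap_query, seed=seed)


class TrainSection(_Section):
    split_mode: str = "ratio_3_1_1"
    folds: int = 5
    pb_epochs: int = 120
    pb_lr: float = 3e-3
    pb_batch: int = 32
    head_epochs: int = 60
    head_lr: float = 1e-3
    joint_epochs: int = 6
    joint_lr: float = 1e-4
    joint_batch: int = 10
    weight_decay: float = 1e-4
    ct_pretrain: bool = True
    pb_pretrain: bool = True
    shortlist_size: int = 4

    def to_split(self, seed: int) -> SplitSpec:
        return SplitSpec(mode=self.split_mode, folds=self.folds, seed=seed)

    def to_spec(self, seed: int) -> TrainSpec:
        return TrainSpec(pb_epochs=self.pb_epochs, pb_lr=self.pb_lr,
                         pb_batch=self.pb_batch, head_epochs=self.head_epochs,
                         head_lr=self.head_lr, joint_epochs=self.joint_epochs,
                         joint_lr=self.joint_lr, joint_batch=self.joint_batch,
                         weight_decay=self.weight_decay,
                         ct_pretrain=self.ct_pretrain,
                         pb_pretrain=self.pb_pretrain, seed=seed)


class RunConfig(_Section):
    seed: int = 0
    outdir: str = "runs/default"
    volume_format: str = "npz"
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    gnn: GNNSection = Field(default_factory=GNNSection)
    cnn: CNNSection = Field(default_factory=CNNSection)
    fusion: FusionSection = Field(default_factory=FusionSection)
    train: TrainSection = Field(default_factory=TrainSection)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def dump_resolved(config: RunConfig, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"package_version": __version__, **config.model_dump()}
    path = outdir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
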