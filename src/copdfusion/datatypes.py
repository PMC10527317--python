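"""Shared in-memory containers for the tabular and volumetric modalities."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CTVolume",
    "NormalizedVolume",
    "PairedDataset",
    "PB_INDICATOR_NAMES",
]

#: The 7 physiological + 17 biochemical indicators of the COPD panel this
#: package emulates (routine blood, liver function, CRP, coagulation).
PB_INDICATOR_NAMES: tuple[str, ...] = (
    "age", "sex", "height", "weight", "smoking", "diastolic_test", "BMI",
    "WBC", "NEUT", "HGB", "PCT", "PLT",
    "ALB", "AST", "ALT", "TBIL", "CREA", "CK", "CKMB", "LDH",
    "CRP", "PT", "APTT", "DD_D",
)


@dataclass
class FeatureTable:
    """Samples x features matrix of physiological/biochemical indicators.

    ``repeated`` optionally holds long-format records of cells measured more
    than once during a visit (columns: sample_id, feature, time, value).
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    repeated: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for "
                f"{self.values.shape[1]} columns"
            )
        if len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[0]} rows"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), list(self.feature_names), self.labels.copy(),
            None if self.repeated is None else self.repeated.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        return df


@dataclass
class CTVolume:
    """A 3-D CT volume in Hounsfield units with voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sample_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D (depth, height, width)")
        if not np.isfinite(self.voxels).all():
            raise ValueError(f"non-finite voxels in volume {self.sample_id!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class NormalizedVolume:
    """Voxels linearly mapped to [0, 1]; keeps the HU window used."""

    voxels: np.ndarray
    hu_min: float
    hu_max: float
    sample_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.min() < 0.0 or self.voxels.max() > 1.0:
            raise ValueError("normalized voxels must lie in [0, 1]")


@dataclass
class PairedDataset:
    """Paired tabular + volumetric samples with binary stage labels.

    ``latents`` carries the generative per-modality signals when the dataset
    is synthetic (used by Bayes-rule oracles in tests, never by models).
    """

    table: FeatureTable
    volumes: list[CTVolume]
    labels: np.ndarray
    split_assignments: Optional[np.ndarray] = None
    latents: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.volumes) == self.table.n_samples == len(self.labels)):
            raise ValueError(
                f"modality lengths disagree: {len(self.volumes)} volumes, "
                f"{self.table.n_samples} table rows, {len(self.labels)} labels"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = early, 1 = advanced)")

    def __len__(self) -> int:
        return len(self.labels)
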