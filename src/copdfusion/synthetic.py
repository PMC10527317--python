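"""Synthetic paired tabular + CT-volume generator.

Emulates the study conditions of a two-stage COPD cohort at desk scale: a
24-indicator physiological/biochemical (PB) table with correlated blocks,
a few class-informative indicators, ~1.67% gross outliers and occasional
repeated measurements; and 3-D lung-like volumes whose class signal is the
density of low-attenuation (emphysema-like) blobs rather than global
brightness.

Modality coupling is controlled by ``modality_signal``:

``pb_only`` / ``ct_only``
    only one modality carries class signal (the other's effect is forced to
    zero).
``redundant``
    both modalities encode the label itself, so either suffices.
``complementary``
    two independent standard-normal latents ``u_pb`` and ``u_ct`` drive the
    two modalities and the label is ``1{(u_pb+u_ct)/sqrt(2) > t}`` with
    ``t`` set by ``label_balance``.  Each single modality then caps the
    Bayes accuracy (~0.75 at balance 0.5) while both together determine the
    label exactly — the structural reason fusion must help.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CTVolume, FeatureTable, PairedDataset, PB_INDICATOR_NAMES

__all__ = [
    "SyntheticSpec",
    "default_spec",
    "generate_pb_table",
    "generate_volumes",
    "generate_paired_dataset",
    "low_attenuation_fraction",
    "bayes_accuracies",
]

MODALITY_SIGNALS = ("pb_only", "ct_only", "complementary", "redundant")

#: Target day (arbitrary visit-time units) at which repeated measurements are
#: resolved — stands in for "the day of the lung-function test".
TARGET_TIME = 3.0


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int
    n_features: int = 24
    correlated_blocks: tuple = ()
    informative_features: tuple = ()
    outlier_fraction: float = 0.0167
    repeated_meas_rate: float = 0.03
    volume_shape: tuple = (16, 32, 32)
    volume_effect: float = 1.0
    hu_range: tuple = (-1000.0, 400.0)
    modality_signal: str = "complementary"
    label_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.modality_signal not in MODALITY_SIGNALS:
            raise ValueError(
                f"modality_signal must be one of {MODALITY_SIGNALS}, "
                f"got {self.modality_signal!r}"
            )
        if self.modality_signal in ("pb_only", "complementary", "redundant") \
                and len(self.informative_features) == 0:
            raise ValueError(
                f"{self.modality_signal} mode requires at least one "
                "informative PB feature"
            )
        if not 0.0 < self.label_balance < 1.0:
            raise ValueError("label_balance must be in (0, 1)")
        seen: set[int] = set()
        for feats, rho in self.correlated_blocks:
            feats = tuple(feats)
            if seen & set(feats):
                raise ValueError("correlated blocks must not overlap")
            seen |= set(feats)
            corr = np.full((len(feats), len(feats)), rho)
            np.fill_diagonal(corr, 1.0)
            eigmin = np.linalg.eigvalsh(corr).min()
            if eigmin <= 1e-12:
                raise ValueError(
                    f"block {feats} with rho={rho} is not positive definite "
                    f"(min eigenvalue {eigmin:.3g})"
                )
            if max(feats) >= self.n_features or min(feats) < 0:
                raise ValueError(f"block {feats} exceeds n_features")
        for j, _delta in self.informative_features:
            if not 0 <= j < self.n_features:
                raise ValueError(f"informative feature index {j} out of range")


def default_spec(n_samples: int, seed: int = 0, **overrides) -> SyntheticSpec:
    """The study-scale default: 24 indicators, 4 informative (planted at the
    BMI / weight / albumin / APTT positions), two correlated biochemistry
    blocks, 1.67% outliers."""
    names = PB_INDICATOR_NAMES
    informative = tuple(
        (names.index(n), 1.5) for n in ("BMI", "weight", "ALB", "APTT")
    )
    blocks = (
        (tuple(names.index(n) for n in ("AST", "ALT", "TBIL")), 0.6),
        (tuple(names.index(n) for n in ("WBC", "NEUT", "PLT")), 0.5),
    )
    base = dict(
        n_samples=n_samples,
        correlated_blocks=blocks,
        informative_features=informative,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


# ---------------------------------------------------------------------------
# latent / label machinery
# ---------------------------------------------------------------------------

def _label_threshold(balance: float) -> float:
    return float(stats.norm.ppf(1.0 - balance))


def _latent_class_gap(balance: float) -> float:
    """Between-class mean gap of one latent in complementary mode.

    With s = (u1+u2)/sqrt(2) and y = 1{s > t}:
    E[u1|y=1] - E[u1|y=0] = (phi(t)/(1-Phi(t)) + phi(t)/Phi(t)) / sqrt(2).
    """
    t = _label_threshold(balance)
    phi, Phi = stats.norm.pdf(t), stats.norm.cdf(t)
    return float((phi / (1.0 - Phi) + phi / Phi) / np.sqrt(2.0))


def _draw_labels_and_latents(spec: SyntheticSpec, rng: np.random.Generator):
    """Returns (labels, pb_signal, ct_signal) — each signal a per-sample
    scalar in standardized units (or zeros when the modality is silent)."""
    n = spec.n_samples
    if spec.modality_signal == "complementary":
        u_pb = rng.standard_normal(n)
        u_ct = rng.standard_normal(n)
        t = _label_threshold(spec.label_balance)
        y = ((u_pb + u_ct) / np.sqrt(2.0) > t).astype(np.int64)
        gap = _latent_class_gap(spec.label_balance)
        # scale so an informative feature's between-class shift is ~delta
        return y, u_pb / gap, u_ct / gap
    y = (rng.random(n) < spec.label_balance).astype(np.int64)
    if spec.modality_signal == "pb_only":
        return y, y.astype(float), np.zeros(n)
    if spec.modality_signal == "ct_only":
        return y, np.zeros(n), y.astype(float)
    return y, y.astype(float), y.astype(float)  # redundant


# ---------------------------------------------------------------------------
# PB table
# ---------------------------------------------------------------------------

def _feature_names(n_features: int) -> list[str]:
    if n_features == len(PB_INDICATOR_NAMES):
        return list(PB_INDICATOR_NAMES)
    return [f"feat_{i:02d}" for i in range(n_features)]

def _correlated_noise(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """N(0, Sigma) noise, Sigma block-diagonal equicorrelation (Gaussian copula)."""
    eps = rng.standard_normal((spec.n_samples, spec.n_features))
    for feats, rho in spec.correlated_blocks:
        feats = list(feats)
        corr = np.full((len(feats), len(feats)), float(rho))
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr)
        eps[:, feats] = eps[:, feats] @ chol.T
    return eps


def generate_pb_table(spec: SyntheticSpec,
                      _signals: tuple | None = None) -> FeatureTable:
    """Generate the PB indicator table (standardized units).

    Informative features get a between-class standardized mean shift of
    ~delta; ``outlier_fraction`` of cells are replaced by gross values 5-8
    column-sd from the mean; ``repeated_meas_rate`` of cells additionally
    carry 2-4 timestamped measurements around a latent linear visit trend.
    The true outlier mask is kept on the returned table (attribute
    ``outlier_mask_true``) for calibration checks.
    """
    ss = np.random.SeedSequence(spec.seed)
    r_label, r_noise, r_out, r_rep, _r_vol = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]
    if _signals is None:
        labels, pb_sig, _ = _draw_labels_and_latents(spec, r_label)
    else:
        labels, pb_sig = _signals

    x = _correlated_noise(spec, r_noise)
    if spec.modality_signal != "ct_only":
        for j, delta in spec.informative_features:
            x[:, j] += float(delta) * pb_sig

    # gross outliers: uniformly chosen cells pushed 5-8 sigma from the mean
    n_cells = x.size
    n_out = int(round(spec.outlier_fraction * n_cells))
    out_mask = np.zeros(x.shape, dtype=bool)
    if n_out > 0:
        flat = r_out.choice(n_cells, size=n_out, replace=False)
        rows, cols = np.unravel_index(flat, x.shape)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        mag = r_out.uniform(5.0, 8.0, size=n_out)
        sign = r_out.choice([-1.0, 1.0], size=n_out)
        x[rows, cols] = mu[cols] + sign * mag * sd[cols]
        out_mask[rows, cols] = True

    repeated = _repeated_records(spec, x, out_mask, r_rep)
    table = FeatureTable(x, _feature_names(spec.n_features), labels, repeated)
    table.outlier_mask_true = out_mask
    return table


def _repeated_records(spec: SyntheticSpec, x: np.ndarray, out_mask: np.ndarray,
                      rng: np.random.Generator) -> pd.DataFrame | None:
    if spec.repeated_meas_rate <= 0:
        return None
    names = _feature_names(spec.n_features)
    n_rep = int(round(spec.repeated_meas_rate * x.size))
    if n_rep == 0:
        return None
    eligible = np.flatnonzero(~out_mask.ravel())
    chosen = rng.choice(eligible, size=min(n_rep, eligible.size), replace=False)
    recs = []
    for flat in chosen:
        i, j = np.unravel_index(flat, x.shape)
        k = rng.integers(2, 5)
        times = np.sort(rng.uniform(0.0, 2.0 * TARGET_TIME, size=k))
        slope = rng.normal(0.0, 0.15)
        vals = x[i, j] + slope * (times - TARGET_TIME) + rng.normal(0, 0.05, k)
        # the flat table keeps the earliest measurement; resolution recovers
        # the value at TARGET_TIME
        x[i, j] = vals[0]
        for t, v in zip(times, vals):
            recs.append((int(i), names[j], float(t), float(v)))
    return pd.DataFrame(recs, columns=["sample_id", "feature", "time", "value"])


# ---------------------------------------------------------------------------
# CT volumes
# ---------------------------------------------------------------------------

#: blob-count model: lambda = BLOB_BASE + BLOB_GAIN * volume_effect * signal
BLOB_BASE = 10.0
BLOB_GAIN = 8.0
LUNG_HU = -800.0
BLOB_HU = -990.0
#: HU threshold of the low-attenuation statistic (emphysema index analogue)
LAA_THRESHOLD = -950.0


def low_attenuation_fraction(voxels: np.ndarray,
                             threshold: float = LAA_THRESHOLD) -> float:
    """Fraction of voxels below the low-attenuation HU threshold."""
    return float((np.asarray(voxels) < threshold).mean())


def _render_volume(shape: tuple, n_blobs: int, hu_range: tuple,
                   rng: np.random.Generator) -> np.ndarray:
    d, h, w = shape
    vol = LUNG_HU + 40.0 * rng.standard_normal((d, h, w))
    zz, yy, xx = np.meshgrid(np.arange(d), np.arange(h), np.arange(w),
                             indexing="ij")
    scale = min(h, w) / 32.0
    for _ in range(n_blobs):
        cz = rng.uniform(0, d)
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        r = rng.uniform(1.5, 3.0) * scale
        mask = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        vol[mask] = BLOB_HU + 5.0 * rng.standard_normal(int(mask.sum()))
    return np.clip(vol, hu_range[0], hu_range[1]).astype(np.float32)


def generate_volumes(spec: SyntheticSpec, labels: np.ndarray,
                     ct_signal: np.ndarray | None = None) -> list[CTVolume]:
    """Render one lung-like HU volume per sample.

    The class signal is the density of low-attenuation spherical blobs
    (an emphysema-like texture), not global brightness.  ``ct_signal``
    overrides the per-sample signal (used by the paired generator to inject
    the complementary-mode latent); by default it is the class label.
    """
    if spec.volume_shape[0] < 2:
        raise ValueError(
            f"volume depth must be >= 2 for 3-D convolution, "
            f"got {spec.volume_shape[0]}"
        )
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    effect = 0.0 if spec.modality_signal == "pb_only" else spec.volume_effect
    if ct_signal is None:
        ct_signal = labels.astype(float)
    ss = np.random.SeedSequence(spec.seed)
    r_vol = np.random.default_rng(ss.spawn(5)[4])
    volumes = []
    for i in range(len(labels)):
        lam = BLOB_BASE + BLOB_GAIN * effect * float(ct_signal[i])
        n_blobs = max(0, int(round(lam)))
        vox = _render_volume(spec.volume_shape, n_blobs, spec.hu_range, r_vol)
        volumes.append(CTVolume(vox, spacing=(1.0, 1.0, 1.0),
                                sample_id=f"s{i:04d}"))
    return volumes


# ---------------------------------------------------------------------------
# paired dataset + Bayes oracle
# ---------------------------------------------------------------------------

def generate_paired_dataset(spec: SyntheticSpec) -> PairedDataset:
    ss = np.random.SeedSequence(spec.seed)
    r_label = np.random.default_rng(ss.spawn(5)[0])
    labels, pb_sig, ct_sig = _draw_labels_and_latents(spec, r_label)
    table = generate_pb_table(spec, _signals=(labels, pb_sig))
    if spec.modality_signal == "pb_only":
        vol_spec = replace(spec, volume_effect=0.0)
    else:
        vol_spec = spec
    volumes = generate_volumes(vol_spec, labels, ct_signal=ct_sig)
    return PairedDataset(
        table=table, volumes=volumes, labels=labels,
        latents={"pb": pb_sig, "ct": ct_sig},
    )


def bayes_accuracies(spec: SyntheticSpec, n: int = 10_000,
                     seed: int | None = None) -> dict[str, float]:
    """Optimal-decision accuracies from the generative model itself.

    Draws latents/labels from the model and applies the Bayes rule given
    (a) the PB latent only, (b) the CT latent only, (c) both.  Serves as the
    independent oracle for the complementary-mode design property.
    """
    probe = replace(spec, n_samples=n,
                    seed=spec.seed if seed is None else seed)
    rng = np.random.default_rng(np.random.SeedSequence(probe.seed).spawn(5)[0])
    y, pb, ct = _draw_labels_and_latents(probe, rng)
    if spec.modality_signal == "complementary":
        gap = _latent_class_gap(spec.label_balance)
        u1, u2 = pb * gap, ct * gap
        t = _label_threshold(spec.label_balance)
        cut = np.sqrt(2.0) * t
        pred_pb = (u1 > cut).astype(int)
        pred_ct = (u2 > cut).astype(int)
        pred_joint = ((u1 + u2) / np.sqrt(2.0) > t).astype(int)
    else:
        pred_pb = (pb > 0.5).astype(int) if pb.any() else np.full_like(y, int(spec.label_balance >= 0.5))
        pred_ct = (ct > 0.5).astype(int) if ct.any() else np.full_like(y, int(spec.label_balance >= 0.5))
        pred_joint = ((pb + ct) > 0.5).astype(int)
    return {
        "pb": float((pred_pb == y).mean()),
        "ct": float((pred_ct == y).mean()),
        "joint": float((pred_joint == y).mean()),
    }
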