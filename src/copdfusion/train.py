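"""Splits, branch and joint end-to-end training, cross-validation,
indicator ranking and group statistics.

The resolution of the data-splitting conventions: a single stratified
3:1:1 train/validation/test split (``ratio_3_1_1``) and stratified k-fold
cross-validation (``kfold``) are both available; in k-fold mode each
training portion is internally split 3:1 into train/validation, matching
3:1:1 overall.  Every preprocessing statistic (outlier screen, imputation
pool, z-scoring, graph edges, HU window) is fitted on training samples
only and applied to held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.model_selection import StratifiedKFold, train_test_split

from .autodiff import no_grad
from .ct import CNNConfig, build_backbone, lite_config, prepare_volumes, \
    pretrain_cnn
from .datatypes import FeatureTable, PairedDataset
from .fusion import FusionConfig, FusionHead, MultiModalClassifier
from .gnn import GNNConfig, PBGraphNet, _topk_indices
from .graph import FeatureGraph, build_feature_graph
from .layers import cross_entropy
from .metrics import MetricsRecord, evaluate_scores
from .optim import Adam
from .preprocess import Preprocessor
from .synthetic import SyntheticSpec, default_spec, generate_paired_dataset

__all__ = [
    "SplitSpec", "make_splits", "TrainSpec", "PipelineResult",
    "train_pb_branch", "train_ct_branch", "train_joint", "cross_validate",
    "rank_indicators", "group_statistics", "GroupStats", "IndicatorReport",
    "fusion_gain_experiment", "indicator_recovery_experiment",
]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    mode: str = "ratio_3_1_1"
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("ratio_3_1_1", "kfold"):
            raise ValueError(f"unknown split mode {self.mode!r}")


def _check_both_classes(labels: np.ndarray, idx: np.ndarray, what: str) -> None:
    if len(np.unique(labels[idx])) < 2:
        raise ValueError(f"class absent from {what} partition")


def make_splits(labels, spec: SplitSpec) -> list[dict[str, np.ndarray]]:
    """Stratified partitions; a list with one entry per fold (one entry in
    ratio mode), each a dict with 'train', 'val', 'test' index arrays."""
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    if spec.mode == "ratio_3_1_1":
        idx = np.arange(n)
        trainval, test = train_test_split(
            idx, test_size=0.2, stratify=labels, random_state=spec.seed)
        train, val = train_test_split(
            trainval, test_size=0.25, stratify=labels[trainval],
            random_state=spec.seed + 1)
        parts = [{"train": np.sort(train), "val": np.sort(val),
                  "test": np.sort(test)}]
    else:
        counts = np.bincount(labels, minlength=2)
        if counts.min() < spec.folds:
            raise ValueError(
                f"need >= {spec.folds} samples per class for {spec.folds}-fold "
                f"CV, got {counts.tolist()}"
            )
        skf = StratifiedKFold(n_splits=spec.folds, shuffle=True,
                              random_state=spec.seed)
        parts = []
        for f, (trainval, test) in enumerate(skf.split(np.zeros(n), labels)):
            train, val = train_test_split(
                trainval, test_size=0.25, stratify=labels[trainval],
                random_state=spec.seed + 100 + f)
            parts.append({"train": np.sort(train), "val": np.sort(val),
                          "test": np.sort(test)})
    for part in parts:
        for name, idx in part.items():
            _check_both_classes(labels, idx, name)
    return parts


# ---------------------------------------------------------------------------
# branch training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainSpec:
    pb_epochs: int = 120
    pb_lr: float = 3e-3
    pb_batch: int = 32
    head_epochs: int = 60       # fusion-head warm-up on frozen branch features
    head_lr: float = 1e-3
    joint_epochs: int = 12      # end-to-end fine-tune of everything
    joint_lr: float = 3e-4
    joint_batch: int = 10
    weight_decay: float = 1e-4
    ct_pretrain: bool = True
    pb_pretrain: bool = True
    seed: int = 0


def _predict_proba(model, *inputs, batch: int = 64) -> np.ndarray:
    """Positive-class probability, eval mode, batched over samples."""
    was_training = model.training
    model.eval()
    out = []
    n = len(inputs[0])
    try:
        with no_grad():
            for s in range(0, n, batch):
                args = [x[s:s + batch] for x in inputs]
                res = model(*args)
                logits = res[-1].data
                m = logits.max(axis=1, keepdims=True)
                e = np.exp(logits - m)
                out.append((e[:, 1] / e.sum(axis=1)))
    finally:
        model.train(was_training)
    return np.concatenate(out)


def _sgd_loop(model, opt, forward_loss, n: int, batch: int, epochs: int,
              rng: np.random.Generator, val_acc=None) -> list[float]:
    """Generic minibatch loop.

    NaN guard: on a non-finite loss the last epoch-end parameter snapshot
    is restored and training stops.  If ``val_acc`` (a zero-argument
    callable) is given, the epoch snapshot with the best validation
    accuracy is restored at the end (ties keep the later epoch).
    """
    history: list[float] = []
    snapshot = model.state_dict()
    best: tuple[float, dict] | None = None
    model.train()
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for s in range(0, n, batch):
            idx = order[s:s + batch]
            loss = forward_loss(idx)
            if not np.isfinite(loss.item()):
                model.load_state_dict(snapshot)
                if best is not None and best[1] is not snapshot:
                    model.load_state_dict(best[1])
                return history
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        snapshot = model.state_dict()
        history.append(total / n)
        if val_acc is not None:
            acc = val_acc()
            if best is None or acc >= best[0]:
                best = (acc, snapshot)
    if best is not None:
        model.load_state_dict(best[1])
    return history


def train_pb_branch(x: np.ndarray, y: np.ndarray, graph: FeatureGraph,
                    config: GNNConfig = GNNConfig(), epochs: int = 120,
                    lr: float = 3e-3, batch: int = 32, seed: int = 0,
                    x_val: np.ndarray | None = None,
                    y_val: np.ndarray | None = None,
                    ) -> tuple[PBGraphNet, list[float]]:
    """Train the GNN branch alone on z-scored indicator rows; when a
    validation set is given the best-validation-epoch weights are kept."""
    model = PBGraphNet(graph, config)
    opt = Adam(model.parameters(), lr=lr, weight_decay=1e-4)
    rng = np.random.default_rng(seed)

    def step(idx):
        _, logits = model(x[idx])
        return cross_entropy(logits, y[idx])

    val_metric = None
    if x_val is not None:
        # negative validation NLL: finer-grained than accuracy, which
        # matters when the labels the branch can see are intrinsically noisy
        def val_metric():
            proba = _predict_proba(model, x_val, batch=256)
            p = np.where(y_val == 1, proba, 1.0 - proba)
            return -float(-np.log(np.clip(p, 1e-12, None)).mean())

    history = _sgd_loop(model, opt, step, len(y), batch, epochs, rng,
                        val_acc=val_metric)
    return model, history


def train_ct_branch(volumes_prepared: np.ndarray, y: np.ndarray,
                    config: CNNConfig):
    """Alias of image-only pretraining on an already prepared stack."""
    return pretrain_cnn(volumes_prepared, y, config)


# ---------------------------------------------------------------------------
# joint end-to-end training
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    model: MultiModalClassifier
    graph: FeatureGraph
    preprocessor: Preprocessor
    scaler: tuple[np.ndarray, np.ndarray]
    hu_window: tuple[float, float]
    x_pb: np.ndarray          # z-scored indicator matrix, all samples
    x_ct: np.ndarray          # prepared volume stack, all samples
    split: dict[str, np.ndarray]
    metrics: dict[str, MetricsRecord] = field(default_factory=dict)
    history: list[float] = field(default_factory=list)

    def proba(self, idx) -> np.ndarray:
        return _predict_proba(self.model, self.x_pb[idx], self.x_ct[idx],
                              batch=32)


def _prepare_modalities(dataset: PairedDataset, split: dict,
                        cnn_config: CNNConfig, knn_k: int = 10):
    """Fit preprocessing on the training partition, apply everywhere."""
    tr = split["train"]
    table = dataset.table
    train_table = FeatureTable(table.values[tr], table.feature_names,
                               table.labels[tr],
                               _subset_repeated(table.repeated, tr))
    prep = Preprocessor(k=knn_k)
    clean_train = prep.fit_transform(train_table)
    full = prep.transform(table.copy())
    # stitch: training rows from the fitted transform, others from transform
    values = full.values.copy()
    values[tr] = clean_train.values
    mu = values[tr].mean(axis=0)
    sd = values[tr].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    x_pb = (values - mu) / sd
    graph = build_feature_graph(
        FeatureTable(values[tr], table.feature_names, table.labels[tr]))
    if cnn_config.hu_window is not None:
        window = cnn_config.hu_window
    else:
        from .ct import hu_window_from_volumes
        window = hu_window_from_volumes([dataset.volumes[i] for i in tr])
    x_ct = prepare_volumes(dataset.volumes, cnn_config, hu_window=window)
    return prep, (mu, sd), x_pb, graph, window, x_ct


def _subset_repeated(repeated, idx):
    if repeated is None:
        return None
    sub = repeated[repeated["sample_id"].isin(set(int(i) for i in idx))]
    remap = {int(v): k for k, v in enumerate(idx)}
    sub = sub.copy()
    sub["sample_id"] = sub["sample_id"].map(remap)
    return sub if len(sub) else None


def _warm_up_head(model: MultiModalClassifier, x_pb, x_ct, y, tr, va,
                  tspec: "TrainSpec") -> None:
    """Train the fusion head alone on cached (frozen) branch features.

    End-to-end joint training then starts from a head that already knows
    how to combine the modalities, which is what makes a short fine-tune
    sufficient; the cached pass avoids re-running the CNN every step.
    """
    from .autodiff import Tensor

    model.eval()
    with no_grad():
        z_a = model.pb_net(x_pb)[0].data
        z_v = model.ct_net(x_ct)[0].data
    model.train()
    head = model.fusion
    opt = Adam(head.parameters(), lr=tspec.head_lr,
               weight_decay=tspec.weight_decay)
    rng = np.random.default_rng(tspec.seed + 7)

    def step(idx):
        _, logits = head(Tensor(z_a[tr][idx]), Tensor(z_v[tr][idx]))
        return cross_entropy(logits, y[tr][idx])

    def val_acc():
        head.eval()
        try:
            with no_grad():
                _, logits = head(Tensor(z_a[va]), Tensor(z_v[va]))
        finally:
            head.train()
        return float((logits.data.argmax(axis=1) == y[va]).mean())

    _sgd_loop(head, opt, step, len(tr), tspec.joint_batch,
              tspec.head_epochs, rng, val_acc=val_acc)


def train_joint(dataset: PairedDataset, split: dict,
                gnn_config: GNNConfig = GNNConfig(),
                cnn_config: CNNConfig = lite_config(),
                fusion_config: FusionConfig = FusionConfig(),
                tspec: TrainSpec = TrainSpec()) -> PipelineResult:
    """End-to-end joint training of both branches and the fusion head.

    The CT branch is optionally initialised from image-only pretraining on
    the training partition; all parameters are then updated jointly under a
    single cross-entropy loss on the fused head.
    """
    y = dataset.labels
    prep, scaler, x_pb, graph, window, x_ct = _prepare_modalities(
        dataset, split, cnn_config)
    tr, va = split["train"], split["val"]

    ct_net = build_backbone(cnn_config)
    if tspec.ct_pretrain:
        ct_net, _ = pretrain_cnn(x_ct[tr], y[tr], cnn_config, model=ct_net,
                                 x_val=x_ct[va], y_val=y[va])
    if tspec.pb_pretrain:
        pb_net, _ = train_pb_branch(
            x_pb[tr], y[tr], graph, replace(gnn_config, seed=tspec.seed),
            epochs=tspec.pb_epochs, lr=tspec.pb_lr, batch=tspec.pb_batch,
            seed=tspec.seed, x_val=x_pb[va], y_val=y[va])
    else:
        pb_net = PBGraphNet(graph, replace(gnn_config, seed=tspec.seed))
    head = FusionHead(gnn_config.out_dim, cnn_config.out_dim,
                      replace(fusion_config, seed=tspec.seed + 1))
    model = MultiModalClassifier(pb_net, ct_net, head)

    if tspec.head_epochs > 0:
        _warm_up_head(model, x_pb, x_ct, y, tr, va, tspec)

    opt = Adam(model.parameters(), lr=tspec.joint_lr,
               weight_decay=tspec.weight_decay)
    rng = np.random.default_rng(tspec.seed)

    def step(idx):
        _, logits = model(x_pb[tr][idx], x_ct[tr][idx])
        return cross_entropy(logits, y[tr][idx])

    def val_acc():
        proba = _predict_proba(model, x_pb[va], x_ct[va], batch=32)
        return float(((proba > 0.5).astype(int) == y[va]).mean())

    history = _sgd_loop(model, opt, step, len(tr), tspec.joint_batch,
                        tspec.joint_epochs, rng, val_acc=val_acc)

    result = PipelineResult(model, graph, prep, scaler, window, x_pb, x_ct,
                            split, history=history)
    for name in ("val", "test"):
        idx = split[name]
        result.metrics[name] = evaluate_scores(result.proba(idx), y[idx])
    return result


def _mean_metrics(records: Sequence[MetricsRecord]) -> MetricsRecord:
    def avg(attr):
        vals = [getattr(r, attr) for r in records if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None
    return MetricsRecord(**{k: avg(k) for k in
                            ("acc", "pre", "sen", "spe", "f1", "auc")})


def cross_validate(dataset: PairedDataset, split_spec: SplitSpec,
                   **kwargs) -> tuple[list[PipelineResult], MetricsRecord]:
    """k-fold outer CV of the joint pipeline; returns per-fold results and
    the fold-averaged test metrics."""
    parts = make_splits(dataset.labels, split_spec)
    results = [train_joint(dataset, part, **kwargs) for part in parts]
    return results, _mean_metrics([r.metrics["test"] for r in results])


# ---------------------------------------------------------------------------
# indicator ranking (pooling shortlist + ablation drops) and group stats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupStats:
    difference: float          # early-group mean minus advanced-group mean
    ci_low: float
    ci_high: float
    t: float
    p: float
    defined: bool = True


def group_statistics(values, labels, equal_var: bool = True) -> GroupStats:
    """Two-sample t statistics on z-scored indicator values (early = label 0
    vs advanced = label 1), with a 95% CI on the mean difference."""
    values = np.asarray(values, float)
    labels = np.asarray(labels).astype(int)
    a = values[labels == 0]
    b = values[labels == 1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    sd = values.std(ddof=0)
    z = (values - values.mean()) / (sd if sd > 0 else 1.0)
    a = z[labels == 0]
    b = z[labels == 1]
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return GroupStats(float(a.mean() - b.mean()), np.nan, np.nan,
                          np.nan, np.nan, defined=False)
    t, p = _sps.ttest_ind(a, b, equal_var=equal_var)
    na, nb = len(a), len(b)
    diff = float(a.mean() - b.mean())
    if equal_var:
        df = na + nb - 2
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / df)
        se = sp * np.sqrt(1.0 / na + 1.0 / nb)
    else:
        se = np.sqrt(va / na + vb / nb)
        df = se**4 / ((va / na)**2 / (na - 1) + (vb / nb)**2 / (nb - 1))
    half = float(_sps.t.ppf(0.975, df) * se)
    return GroupStats(diff, diff - half, diff + half, float(t), float(p))


@dataclass
class IndicatorReport:
    frame: pd.DataFrame        # indicator, pooled_z, selected, drop, rank, stats
    shortlist: list[str]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def rank_indicators(model: PBGraphNet, x_eval: np.ndarray, y_eval: np.ndarray,
                    feature_names: Sequence[str],
                    train_means: np.ndarray | None = None,
                    raw_values: np.ndarray | None = None,
                    q: int = 4) -> IndicatorReport:
    """Pooling shortlist + sequential-removal importance.

    Indicators surviving TopK pooling (by mean pooled score z) are each
    "removed" by substituting the column with its training mean and the
    accuracy decrease is recorded; indicators are ranked by decrease (ties
    broken toward larger pooled z) and the top ``q`` form the shortlist.
    Ablation is at inference time (no retraining), so the report is
    deterministic for a fixed model.
    """
    n_nodes = model.graph.n_nodes
    if train_means is None:
        train_means = np.zeros(n_nodes)  # z-scored space: train mean is 0
    z = model.node_scores(x_eval)
    m = int(np.ceil(model.config.pool_ratio * n_nodes))
    selected = set(_topk_indices(z, m).tolist())

    def accuracy(mat):
        proba = _predict_proba(model, mat, batch=256)
        return float(((proba > 0.5).astype(int) == y_eval).mean())

    base = accuracy(x_eval)
    drops = np.full(n_nodes, np.nan)
    for j in sorted(selected):
        ablated = x_eval.copy()
        ablated[:, j] = train_means[j]
        drops[j] = base - accuracy(ablated)

    order = sorted(selected, key=lambda j: (-drops[j], -z[j], j))
    ranks = {j: r + 1 for r, j in enumerate(order)}
    stats_source = raw_values if raw_values is not None else x_eval
    rows = []
    for j in range(n_nodes):
        gs = group_statistics(stats_source[:, j], y_eval)
        rows.append({
            "indicator": feature_names[j],
            "pooled_z": float(z[j]),
            "selected": j in selected,
            "accuracy_drop": float(drops[j]) if j in selected else np.nan,
            "rank": ranks.get(j, np.nan),
            "difference": gs.difference, "ci_low": gs.ci_low,
            "ci_high": gs.ci_high, "t": gs.t, "p": gs.p,
            "stats_defined": gs.defined,
        })
    frame = pd.DataFrame(rows)
    shortlist = [feature_names[j] for j in order[:q]]
    return IndicatorReport(frame=frame, shortlist=shortlist)


# ---------------------------------------------------------------------------
# study-condition experiments (used by the acceptance checks)
# ---------------------------------------------------------------------------

def _zscored_clean(dataset: PairedDataset, tr: np.ndarray):
    table = dataset.table
    train_table = FeatureTable(table.values[tr], table.feature_names,
                               table.labels[tr],
                               _subset_repeated(table.repeated, tr))
    prep = Preprocessor()
    clean_train = prep.fit_transform(train_table)
    full = prep.transform(table.copy())
    values = full.values.copy()
    values[tr] = clean_train.values
    mu = values[tr].mean(axis=0)
    sd = values[tr].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd, values


def fusion_gain_experiment(seeds: Sequence[int] = (0, 1, 2, 3, 4),
                           n: int = 300,
                           spec: SyntheticSpec | None = None,
                           pb_epochs: int = 120, ct_epochs: int = 25,
                           joint_epochs: int = 6) -> dict:
    """Fused vs unimodal test accuracy on complementary paired data.

    For each seed a fresh dataset (n samples, 24 indicators, 16x32x32
    volumes) is drawn, split 3:1:1, and three models are trained: the PB
    branch alone, the CT branch alone, and the joint fusion model (CT
    branch initialised from the image-only pretraining).  Returns per-seed
    and mean accuracies plus the fusion gain over the best unimodal mean.
    """
    rows = []
    for s in seeds:
        base = spec if spec is not None else default_spec(
            n, seed=1000 + s, modality_signal="complementary")
        dataset = generate_paired_dataset(replace(base, seed=1000 + s))
        y = dataset.labels
        part = make_splits(y, SplitSpec(seed=s))[0]
        tr, va, te = part["train"], part["val"], part["test"]

        cnn_cfg = lite_config(epochs=ct_epochs, seed=s)
        gnn_cfg = GNNConfig(seed=s)
        x_pb, _ = _zscored_clean(dataset, tr)
        graph = build_feature_graph(
            FeatureTable(x_pb[tr], dataset.table.feature_names, y[tr]))
        pb_net, _ = train_pb_branch(x_pb[tr], y[tr], graph, gnn_cfg,
                                    epochs=pb_epochs, seed=s,
                                    x_val=x_pb[va], y_val=y[va])
        acc_pb = float(((
            _predict_proba(pb_net, x_pb[te], batch=256) > 0.5
        ).astype(int) == y[te]).mean())

        x_ct = prepare_volumes(dataset.volumes, cnn_cfg)
        ct_net, _ = pretrain_cnn(x_ct[tr], y[tr], cnn_cfg,
                                 x_val=x_ct[va], y_val=y[va])
        acc_ct = float(((
            _predict_proba(ct_net, x_ct[te], batch=32) > 0.5
        ).astype(int) == y[te]).mean())

        result = train_joint(
            dataset, part, gnn_config=gnn_cfg, cnn_config=cnn_cfg,
            fusion_config=FusionConfig(seed=s),
            tspec=TrainSpec(joint_epochs=joint_epochs, joint_lr=1e-4,
                            seed=s),
        )
        acc_fused = result.metrics["test"].acc
        rows.append({"seed": s, "pb": acc_pb, "ct": acc_ct,
                     "fused": acc_fused})
    frame = pd.DataFrame(rows)
    means = {k: float(frame[k].mean()) for k in ("pb", "ct", "fused")}
    means["gain_over_best_unimodal"] = means["fused"] - max(means["pb"],
                                                            means["ct"])
    return {"per_seed": rows, "mean": means}


def indicator_recovery_experiment(seeds: Sequence[int] = (0, 1, 2, 3, 4),
                                  n: int = 400, q: int = 4,
                                  epochs: int = 120) -> dict:
    """Recovery of planted informative indicators by pooling + ablation.

    Each seed draws pb_only data with 4 informative indicators among 24,
    trains the PB branch, and checks how many planted indicators the
    shortlist of ``q`` recovers and how large the accuracy perturbation of
    ablating pure-noise indicators is (evaluated on the full dataset to
    suppress small-test-fold quantisation).
    """
    rows = []
    for s in seeds:
        spec = default_spec(n, seed=2000 + s, modality_signal="pb_only")
        planted = {spec.informative_features[i][0]
                   for i in range(len(spec.informative_features))}
        dataset = generate_paired_dataset(spec)
        y = dataset.labels
        part = make_splits(y, SplitSpec(seed=s))[0]
        tr, va = part["train"], part["val"]
        x_pb, _ = _zscored_clean(dataset, tr)
        graph = build_feature_graph(
            FeatureTable(x_pb[tr], dataset.table.feature_names, y[tr]))
        net, _ = train_pb_branch(x_pb[tr], y[tr], graph, GNNConfig(seed=s),
                                 epochs=epochs, seed=s,
                                 x_val=x_pb[va], y_val=y[va])
        report = rank_indicators(net, x_pb, y,
                                 dataset.table.feature_names, q=q)
        names = list(dataset.table.feature_names)
        short_idx = {names.index(nm) for nm in report.shortlist}
        hits = len(short_idx & planted)
        noise_drops = report.frame.loc[
            report.frame["selected"]
            & ~report.frame["indicator"].isin(
                [names[j] for j in planted]),
            "accuracy_drop"].abs()
        rows.append({
            "seed": s, "hits": hits,
            "max_noise_drop": float(noise_drops.max()) if len(noise_drops)
            else 0.0,
            "shortlist": report.shortlist,
        })
    hits = [r["hits"] for r in rows]
    return {
        "per_seed": rows,
        "seeds_with_3_of_4": int(sum(h >= 3 for h in hits)),
        "mean_hits": float(np.mean(hits)),
        "max_noise_drop": float(max(r["max_noise_drop"] for r in rows)),
    }
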