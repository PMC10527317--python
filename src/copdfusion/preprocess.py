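"""Tabular preprocessing for the PB indicator table.

Three steps, applied in this order by :func:`preprocess_table`:

1. repeated measurements from a single visit are resolved to the reference
   day by an ordinary least-squares line in time (mean if all measurements
   share one timestamp);
2. gross outliers are screened by the 3-sigma rule (population sd, strict
   inequality, per column over all samples);
3. flagged or missing cells are imputed by the mean of the K nearest
   neighbours *of the same class*, with distances taken over z-scored,
   mutually observed, non-flagged columns.

Screening statistics, z-scoring statistics and the neighbour pool can be
fitted on training samples only and applied to held-out samples via
:class:`Preprocessor` (leakage control for cross-validation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import FeatureTable
from .synthetic import TARGET_TIME

__all__ = [
    "ColumnStats",
    "detect_outliers_3sigma",
    "knn_impute",
    "resolve_repeated_measurements",
    "preprocess_table",
    "Preprocessor",
    "preprocessing_report",
]


@dataclass(frozen=True)
class ColumnStats:
    mean: np.ndarray
    std: np.ndarray  # population (ddof=0)


def column_stats(values: np.ndarray, feature_names: list[str]) -> ColumnStats:
    values = np.asarray(values, float)
    finite = np.isfinite(values)
    empty = ~finite.any(axis=0)
    if empty.any():
        bad = [feature_names[j] for j in np.flatnonzero(empty)]
        raise ValueError(f"column(s) with no finite values: {bad}")
    mu = np.nanmean(np.where(finite, values, np.nan), axis=0)
    sd = np.nanstd(np.where(finite, values, np.nan), axis=0, ddof=0)
    return ColumnStats(mu, sd)


def detect_outliers_3sigma(table: FeatureTable,
                           stats: ColumnStats | None = None) -> np.ndarray:
    """Boolean mask of cells deviating strictly more than 3 sigma from the
    column mean (population sd; constant columns flag nothing)."""
    if stats is None:
        stats = column_stats(table.values, table.feature_names)
    values = table.values
    with np.errstate(invalid="ignore"):
        dev = np.abs(values - stats.mean)
        mask = dev > 3.0 * stats.std
    mask &= np.isfinite(values)
    mask &= stats.std > 0
    return mask


def _zscore(values: np.ndarray, stats: ColumnStats) -> np.ndarray:
    sd = np.where(stats.std > 0, stats.std, 1.0)
    return (values - stats.mean) / sd


def knn_impute(table: FeatureTable, mask: np.ndarray, k: int = 10,
               pool: FeatureTable | None = None,
               pool_mask: np.ndarray | None = None,
               stats: ColumnStats | None = None) -> FeatureTable:
    """Fill flagged/missing cells from same-class nearest neighbours.

    Distance between a target sample and a candidate neighbour is the RMS
    difference over z-scored columns that are observed and unflagged in
    both; the imputed value is the mean of the target column over the k
    nearest eligible neighbours (all of them if fewer than k exist).
    ``pool`` restricts the neighbour search to a fitted training table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pool = table if pool is None else pool
    pool_mask = mask if pool is table and pool_mask is None else (
        pool_mask if pool_mask is not None else np.zeros(pool.values.shape, bool)
    )
    if stats is None:
        # z-scoring for distances excludes the flagged cells themselves, so
        # imputation is insensitive to (and idempotent under) the outliers
        # being replaced
        masked = np.where(np.isfinite(pool.values) & ~pool_mask,
                          pool.values, np.nan)
        stats = column_stats(masked, pool.feature_names)

    out = table.values.copy()
    need = mask | ~np.isfinite(table.values)
    pool_valid = np.isfinite(pool.values) & ~pool_mask
    z_t = _zscore(np.where(np.isfinite(table.values) & ~mask, table.values,
                           np.nan), stats)
    z_p = _zscore(np.where(pool_valid, pool.values, np.nan), stats)

    same_table = pool is table
    for i, j in zip(*np.nonzero(need)):
        cls = table.labels[i]
        elig = (pool.labels == cls) & pool_valid[:, j]
        if same_table:
            elig[i] = False
        cand = np.flatnonzero(elig)
        if cand.size == 0:
            raise ValueError(
                f"no eligible same-class neighbour for sample {i}, "
                f"feature {table.feature_names[j]!r}"
            )
        diff = z_t[i][None, :] - z_p[cand]
        shared = np.isfinite(diff)
        with np.errstate(invalid="ignore"):
            dist = np.sqrt(np.nanmean(np.where(shared, diff**2, np.nan), axis=1))
        dist = np.where(np.isnan(dist), np.inf, dist)  # no shared columns
        order = np.argsort(dist, kind="stable")        # ties -> lower index
        nearest = cand[order[:min(k, cand.size)]]
        out[i, j] = pool.values[nearest, j].mean()

    result = FeatureTable(out, list(table.feature_names), table.labels.copy(),
                          table.repeated)
    return result


def _ols_at(times: np.ndarray, values: np.ndarray, target: float) -> float:
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(values) == 1:
        return float(values[0])
    if np.ptp(times) == 0.0:
        return float(values.mean())
    slope, intercept = np.polyfit(times, values, 1)
    return float(slope * target + intercept)


def resolve_repeated_measurements(table: FeatureTable,
                                  target_time=TARGET_TIME) -> FeatureTable:
    """Collapse multi-valued cells to the reference day.

    For each (sample, feature) group in ``table.repeated``: a single record
    passes through; two or more records with distinct times are fitted with
    an ordinary least-squares line value~time and evaluated at the sample's
    target time; coincident times are averaged.  ``target_time`` may be a
    scalar or a per-sample mapping/array.
    """
    if table.repeated is None or len(table.repeated) == 0:
        return table.copy()
    out = table.values.copy()
    name_to_col = {n: j for j, n in enumerate(table.feature_names)}

    def target_for(sample: int) -> float:
        if np.isscalar(target_time):
            return float(target_time)
        return float(target_time[sample])

    for (sid, feat), grp in table.repeated.groupby(["sample_id", "feature"],
                                                   sort=False):
        j = name_to_col[feat]
        out[int(sid), j] = _ols_at(grp["time"].to_numpy(),
                                   grp["value"].to_numpy(), target_for(int(sid)))
    return FeatureTable(out, list(table.feature_names), table.labels.copy(),
                        table.repeated)


def preprocessing_report(mask: np.ndarray, feature_names: list[str]) -> dict:
    mask = np.asarray(mask, bool)
    per_col = mask.mean(axis=0)
    return {
        "n_flagged": int(mask.sum()),
        "flag_rate": float(mask.mean()),
        "per_column_flag_rate": {n: float(r) for n, r in
                                 zip(feature_names, per_col)},
    }


def preprocess_table(table: FeatureTable, k: int = 10,
                     target_time=TARGET_TIME) -> tuple[FeatureTable, np.ndarray, dict]:
    """resolve -> screen -> impute on a single table; returns (clean, mask, report)."""
    resolved = resolve_repeated_measurements(table, target_time)
    mask = detect_outliers_3sigma(resolved)
    clean = knn_impute(resolved, mask, k=k)
    return clean, mask, preprocessing_report(mask, table.feature_names)


class Preprocessor:
    """Fold-safe preprocessing: statistics and neighbour pool from training
    samples only; held-out samples are screened and imputed against them."""

    def __init__(self, k: int = 10, target_time=TARGET_TIME):
        self.k = k
        self.target_time = target_time
        self.stats_: ColumnStats | None = None
        self.train_: FeatureTable | None = None
        self.train_mask_: np.ndarray | None = None

    def fit(self, train: FeatureTable) -> "Preprocessor":
        resolved = resolve_repeated_measurements(train, self.target_time)
        self.stats_ = column_stats(resolved.values, resolved.feature_names)
        self.train_mask_ = detect_outliers_3sigma(resolved, self.stats_)
        self.train_ = resolved
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if self.stats_ is None:
            raise RuntimeError("Preprocessor.transform called before fit")
        resolved = resolve_repeated_measurements(table, self.target_time)
        mask = detect_outliers_3sigma(resolved, self.stats_)
        return knn_impute(resolved, mask, k=self.k, pool=self.train_,
                          pool_mask=self.train_mask_)

    def fit_transform(self, train: FeatureTable) -> FeatureTable:
        self.fit(train)
        return knn_impute(self.train_, self.train_mask_, k=self.k)

    def report(self) -> dict:
        return preprocessing_report(self.train_mask_,
                                    self.train_.feature_names)

    def save_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.report(), indent=1))
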