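"""Feature-table harmonization: column-mean imputation, then z-scoring.

The default pipeline fits both steps on the whole dataset before
cross-validation, matching the usual radiomic workflow in which tables are
harmonized once up front. :class:`Preprocessor` exposes the same two steps as
a fit/transform pair so callers who want leakage-free fold-wise normalization
can fit on training folds only.

Standard deviations use the sample convention (divisor n-1). Zero-variance
columns cannot be z-scored and break several scoring methods (Pearson-type
correlations, Bhattacharyya), so they are dropped and reported rather than
kept as zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .synthetic import FeatureTable

__all__ = ["PreprocessReport", "Preprocessor", "impute_mean", "zscore", "preprocess"]

_VAR_TOL = 1e-12


@dataclass
class PreprocessReport:
    """What preprocessing did: imputation counts, drops, scaling constants."""

    imputed_cells: dict[str, int] = field(default_factory=dict)
    dropped_features: list[str] = field(default_factory=list)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "imputed_cells": self.imputed_cells,
                "dropped_features": self.dropped_features,
                "means": self.means,
                "sds": self.sds,
            },
            **kwargs,
        )


def impute_mean(table: FeatureTable) -> FeatureTable:
    """Replace every missing cell by its column's observed mean.

    Raises if a column has no observed value at all (its mean is undefined).
    """
    values = table.values.copy()
    mask = np.isnan(values)
    if not mask.any():
        return table.copy()
    all_missing = mask.all(axis=0)
    if all_missing.any():
        bad = [table.feature_names[j] for j in np.nonzero(all_missing)[0]]
        raise ValueError(f"cannot impute all-missing feature(s): {bad}")
    col_means = np.nanmean(values, axis=0)
    values[mask] = np.broadcast_to(col_means, values.shape)[mask]
    return FeatureTable(values, table.outcome, table.feature_names, table.sample_ids)


def zscore(table: FeatureTable) -> tuple[FeatureTable, PreprocessReport]:
    """Center and scale each column to mean 0, sample sd 1.

    Zero-variance columns are dropped and listed in the report. Requires a
    fully observed table (run :func:`impute_mean` first).
    """
    if np.isnan(table.values).any():
        raise ValueError("zscore requires a table with no missing values")
    values = table.values
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
    keep = sds > _VAR_TOL
    report = PreprocessReport(
        dropped_features=[n for n, k in zip(table.feature_names, keep) if not k],
        means={n: float(m) for n, m, k in zip(table.feature_names, means, keep) if k},
        sds={n: float(s) for n, s, k in zip(table.feature_names, sds, keep) if k},
    )
    scaled = (values[:, keep] - means[keep]) / sds[keep]
    out = FeatureTable(
        scaled,
        table.outcome,
        [n for n, k in zip(table.feature_names, keep) if k],
        table.sample_ids,
    )
    return out, report


def preprocess(table: FeatureTable) -> tuple[FeatureTable, PreprocessReport]:
    """Impute missing cells by column means, then z-score; report both steps."""
    mask = np.isnan(table.values)
    imputed = impute_mean(table)
    out, report = zscore(imputed)
    counts = mask.sum(axis=0)
    report.imputed_cells = {
        n: int(c) for n, c in zip(table.feature_names, counts)
    }
    return out, report


class Preprocessor:
    """Fit/transform variant for fold-wise (leakage-free) preprocessing.

    ``fit`` learns column means (for imputation and centering) and sample
    standard deviations from the given rows; ``transform`` applies them to any
    table with the same features. Columns constant in the fitting data are
    dropped from transformed output.
    """

    def __init__(self) -> None:
        self.feature_names_: list[str] | None = None
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None
        self.keep_: np.ndarray | None = None

    def fit(self, table: FeatureTable) -> "Preprocessor":
        values = table.values
        if np.isnan(values).all(axis=0).any():
            raise ValueError("a feature has no observed value in the fitting data")
        self.feature_names_ = list(table.feature_names)
        self.means_ = np.nanmean(values, axis=0)
        filled = np.where(np.isnan(values), self.means_, values)
        sds = filled.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
        self.keep_ = sds > _VAR_TOL
        self.sds_ = sds
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if self.means_ is None:
            raise RuntimeError("Preprocessor is not fitted")
        if list(table.feature_names) != self.feature_names_:
            raise ValueError("feature names differ from the fitting table")
        values = np.where(np.isnan(table.values), self.means_, table.values)
        scaled = (values[:, self.keep_] - self.means_[self.keep_]) / self.sds_[self.keep_]
        return FeatureTable(
            scaled,
            table.outcome,
            [n for n, k in zip(table.feature_names, self.keep_) if k],
            table.sample_ids,
        )
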