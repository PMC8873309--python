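"""Study orchestration: run the model grid over datasets and summarize.

Per dataset: preprocess (mean imputation + z-scoring) -> enumerate the config
grid -> run every configuration through one shared stratified 10-fold split
-> keep the best config per (scoring method, classifier) pair -> delimit the
set of models statistically equivalent to the best (paired DeLong, alpha
0.05, unadjusted) -> summarize selection stability, between-model similarity
and feature-set correlation over that set.

Across datasets, ordinary least-squares regressions relate each dataset's
mean AUC over the equivalence set to (a) the number of equivalent models and
(b-d) the three agreement means; the expected pattern on heterogeneous data
is a negative slope for the count and positive slopes for the measures.

Every stochastic component derives its child seed from one master seed, so a
study is bit-reproducible end to end. Results can be persisted as JSON-lines
(one record per configuration) plus a run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._rng import derive_seed
from .agreement import summarize_equivalence
from .delong import equivalence_set
from .harness import (
    CLASSIFIERS,
    ModelConfig,
    best_per_pair,
    enumerate_configs,
    make_split,
    pooled_auc,
    run_cv,
)
from .preprocess import preprocess
from .scoring import FS_METHODS, N_FEATURES_GRID
from .synthetic import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "DatasetSummary",
    "RegressionResult",
    "run_study",
    "regress_measures",
    "read_feature_table",
    "write_feature_table",
]


@dataclass
class StudyConfig:
    """Grid axes, test level and master seed of one study run.

    The default axes are the full benchmark grid (3640 configurations per
    dataset); tests and desk-scale runs pass reduced axes.
    """

    fs_methods: tuple = FS_METHODS
    n_grid: tuple = N_FEATURES_GRID
    classifiers: tuple = CLASSIFIERS
    alpha: float = 0.05
    seed: int = 0
    n_splits: int = 10
    out_dir: str | None = None


@dataclass
class DatasetSummary:
    dataset_id: str
    best_config: ModelConfig
    best_auc: float
    mean_auc: float  # mean pooled AUC over {best} ∪ equivalent models
    n_equivalent: int
    stability: dict = field(default_factory=dict)  # mean/min/max
    similarity: dict = field(default_factory=dict)
    correlation: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "best_config": self.best_config.key(),
            "best_auc": self.best_auc,
            "mean_auc": self.mean_auc,
            "n_equivalent": self.n_equivalent,
            **{f"stability_{k}": v for k, v in self.stability.items()},
            **{f"similarity_{k}": v for k, v in self.similarity.items()},
            **{f"correlation_{k}": v for k, v in self.correlation.items()},
        }


@dataclass
class RegressionResult:
    response: str
    slope: float
    intercept: float
    p_value: float
    n_points: int


def analyze_dataset(
    dataset_id: str, table: FeatureTable, config: StudyConfig
) -> DatasetSummary:
    """Run the full per-dataset pipeline and summarize the equivalence set."""
    prepped, _ = preprocess(table)
    split_seed = derive_seed(config.seed, dataset_id, "split")
    split = make_split(prepped, split_seed, config.n_splits)
    configs = enumerate_configs(config.fs_methods, config.n_grid, config.classifiers)
    model_seed = derive_seed(config.seed, dataset_id, "models")

    records = []
    predictions = {}
    score_cache: dict = {}
    for cfg in configs:
        pred = run_cv(prepped, cfg, split, seed=model_seed, score_cache=score_cache)
        predictions[cfg.key()] = pred
        records.append((cfg, pooled_auc(pred.scores, pred.labels)))

    best = best_per_pair(records)
    pair_order = [
        (fs, clf) for fs in config.fs_methods for clf in config.classifiers
    ]
    best_preds = [predictions[best[pair][0].key()] for pair in pair_order]
    eq = equivalence_set(best_preds, config.alpha)

    fold_selections = {
        key: pred.fold_selections for key, pred in predictions.items()
    }
    measures = summarize_equivalence(eq, fold_selections, prepped)
    eq_keys = [eq.best.key()] + [cfg.key() for cfg, _ in eq.members]
    mean_auc = float(
        np.mean([pooled_auc(predictions[k].scores, predictions[k].labels) for k in eq_keys])
    )

    summary = DatasetSummary(
        dataset_id=dataset_id,
        best_config=eq.best,
        best_auc=eq.best_auc,
        mean_auc=mean_auc,
        n_equivalent=len(eq.members),
        stability=measures["stability"],
        similarity=measures["similarity"],
        correlation=measures["correlation"],
    )
    if config.out_dir:
        _persist(dataset_id, records, predictions, summary, config)
    return summary


def run_study(
    datasets: list[tuple[str, FeatureTable]], config: StudyConfig | None = None
) -> list[DatasetSummary]:
    """Run the configured grid over every dataset; failures are isolated."""
    config = config or StudyConfig()
    summaries = []
    for dataset_id, table in datasets:
        try:
            logger.info("dataset %s: starting", dataset_id)
            summaries.append(analyze_dataset(dataset_id, table, config))
        except Exception:
            logger.exception("dataset %s failed; continuing", dataset_id)
    return summaries


def regress_measures(summaries: list[DatasetSummary]) -> list[RegressionResult]:
    """OLS of each response on the datasets' mean equivalence-set AUC.

    Responses: number of equivalent models and the three agreement means.
    The slope p-value is the two-sided t-test of the OLS coefficient.
    """
    if len(summaries) < 3:
        raise ValueError("regression needs at least 3 datasets")
    x = np.array([s.mean_auc for s in summaries])
    responses = {
        "n_equivalent": np.array([s.n_equivalent for s in summaries], dtype=float),
        "stability": np.array([s.stability["mean"] for s in summaries]),
        "similarity": np.array([s.similarity["mean"] for s in summaries]),
        "correlation": np.array([s.correlation["mean"] for s in summaries]),
    }
    results = []
    design = sm.add_constant(x)
    for name, y in responses.items():
        fit = sm.OLS(y, design).fit()
        results.append(
            RegressionResult(
                response=name,
                slope=float(fit.params[1]),
                intercept=float(fit.params[0]),
                p_value=float(fit.pvalues[1]),
                n_points=len(summaries),
            )
        )
    return results


# --------------------------------------------------------------------------
# I/O: the CSV dialect (sample id first, features, `outcome` 0/1 last;
# missing cells empty) and JSON-lines persistence.


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, "sample_id", table.sample_ids)
    df["outcome"] = table.outcome
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a CSV feature table; non-numeric feature cells become missing."""
    df = pd.read_csv(path)
    if "outcome" not in df.columns:
        raise ValueError(f"{path}: no 'outcome' column")
    id_col = df.columns[0]
    sample_ids = df[id_col].astype(str).tolist()
    feature_cols = [c for c in df.columns if c not in (id_col, "outcome")]
    if len(set(feature_cols)) != len(feature_cols):
        raise ValueError(f"{path}: duplicate feature names")
    outcome_raw = pd.to_numeric(df["outcome"], errors="coerce")
    bad = ~outcome_raw.isin([0, 1])
    if bad.any():
        rows = df.index[bad].tolist()[:10]
        raise ValueError(
            f"{path}: outcome must be binary 0/1; offending rows {rows}"
        )
    values = (
        df[feature_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    )
    return FeatureTable(values, outcome_raw.to_numpy(dtype=int), feature_cols, sample_ids)


def _persist(dataset_id, records, predictions, summary, config: StudyConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{dataset_id}.jsonl", "w") as fh:
        for cfg, auc in records:
            fh.write(
                json.dumps(
                    {
                        "config": cfg.key(),
                        "auc": auc,
                        "fold_selected": [
                            sel.indices.tolist()
                            for sel in predictions[cfg.key()].fold_selections
                        ],
                    }
                )
                + "\n"
            )
    with open(out / f"{dataset_id}.summary.json", "w") as fh:
        json.dump(summary.to_record(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "dataset_id": dataset_id,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_splits": config.n_splits,
        "fs_methods": list(config.fs_methods),
        "n_grid": list(config.n_grid),
        "classifiers": list(config.classifiers),
    }
    with open(out / f"{dataset_id}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def summaries_to_frame(summaries: list[DatasetSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_record() for s in summaries])


def regressions_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
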