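"""Model grid enumeration and cross-validated training.

The benchmark grid crosses 8 feature-scoring methods, 7 feature counts
(N = 1, 2, 4, ..., 64) and 8 classifiers with fixed hyperparameter grids:

========================  ==========================================  ======
classifier                grid                                        points
========================  ==========================================  ======
lda                       (none)                                           1
linear_svm                C in 2**{-6,-4,-2,0,2,4,6}                       7
logistic                  C in 2**{-6,-4,-2,0,2,4,6}                       7
naive_bayes               (none)                                           1
neural_net                neurons per layer 1..3 in {4,16,64}             27
random_forest             trees in {50,250,500}                            3
rbf_svm                   C in 2**{-6,-4,-2,0,2,4,6}, gamma auto           7
xgboost                   lr in {0.001,0.1,0.3,0.9} x trees {50,250,500}  12
========================  ==========================================  ======

for 65 classifier points and 8 x 7 x 65 = 3640 configurations per dataset.

All configurations of one dataset share a single stratified 10-fold split:
the paired DeLong test compares two models' out-of-fold scores sample by
sample, which is only coherent when both models scored each sample under the
same partition. Per fold, features are scored and selected on the nine
training folds only, the classifier is fitted on the selected columns, and
the held-out fold receives continuous scores (event-class probability when
the classifier provides one, otherwise its decision value); the ten held-out
score vectors are pooled into one ROC per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._rng import derive_seed
from .scoring import (
    FS_METHODS,
    N_FEATURES_GRID,
    Selection,
    score_features,
    select_top,
)
from .synthetic import FeatureTable

__all__ = [
    "CLASSIFIERS",
    "ModelConfig",
    "CVSplit",
    "PooledPrediction",
    "classifier_grid",
    "enumerate_configs",
    "make_split",
    "run_cv",
    "pooled_auc",
    "best_per_pair",
]

_C_GRID = tuple(float(2.0**k) for k in (-6, -4, -2, 0, 2, 4, 6))
_TREE_GRID = (50, 250, 500)

CLASSIFIERS = (
    "lda",
    "linear_svm",
    "logistic",
    "naive_bayes",
    "neural_net",
    "random_forest",
    "rbf_svm",
    "xgboost",
)


def classifier_grid(name: str) -> list[dict]:
    """All hyperparameter points of one classifier's fixed grid."""
    if name in ("lda", "naive_bayes"):
        return [{}]
    if name in ("linear_svm", "logistic", "rbf_svm"):
        return [{"C": c} for c in _C_GRID]
    if name == "neural_net":
        return [
            {"layers": (a, b, c)}
            for a, b, c in product((4, 16, 64), repeat=3)
        ]
    if name == "random_forest":
        return [{"n_estimators": t} for t in _TREE_GRID]
    if name == "xgboost":
        return [
            {"learning_rate": lr, "n_estimators": t}
            for lr in (0.001, 0.1, 0.3, 0.9)
            for t in _TREE_GRID
        ]
    raise ValueError(f"unknown classifier {name!r}")


@dataclass(frozen=True)
class ModelConfig:
    """One grid point: scoring method, N selected, classifier + hyperparams."""

    fs_method: str
    n_features: int
    classifier: str
    hyperparams: tuple = ()  # sorted (name, value) pairs, hashable

    @property
    def hyperparam_dict(self) -> dict:
        return dict(self.hyperparams)

    def key(self) -> str:
        hp = ",".join(f"{k}={v}" for k, v in self.hyperparams)
        return f"{self.fs_method}|{self.n_features}|{self.classifier}|{hp}"


def _as_config(fs: str, n: int, clf: str, hp: dict) -> ModelConfig:
    return ModelConfig(fs, n, clf, tuple(sorted(hp.items())))


def enumerate_configs(
    fs_methods=FS_METHODS,
    n_grid=N_FEATURES_GRID,
    classifiers=CLASSIFIERS,
) -> list[ModelConfig]:
    """The full Cartesian grid in deterministic order (3640 points by default)."""
    configs = []
    for fs in fs_methods:
        for n in n_grid:
            for clf in classifiers:
                for hp in classifier_grid(clf):
                    configs.append(_as_config(fs, n, clf, hp))
    return configs


@dataclass
class CVSplit:
    """A stratified 10-fold partition shared by every model on a dataset."""

    fold_assignment: np.ndarray
    seed: int
    n_splits: int = 10

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_assignment == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_assignment != fold)[0]


def make_split(table: FeatureTable, seed: int, n_splits: int = 10) -> CVSplit:
    """Stratified k-fold assignment; per-fold event counts differ by <= 1."""
    counts = np.bincount(table.outcome, minlength=2)
    if counts.min() < n_splits:
        raise ValueError(
            f"need >= {n_splits} samples per class for {n_splits}-fold stratified CV; "
            f"class counts are {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    assignment = np.empty(table.n_samples, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(table.values, table.outcome)):
        assignment[test_idx] = fold
    return CVSplit(assignment, seed, n_splits)


@dataclass
class PooledPrediction:
    """Out-of-fold scores for every sample from one model's full CV run."""

    scores: np.ndarray
    labels: np.ndarray
    config: ModelConfig
    fold_selections: list[Selection] = field(default_factory=list)


def _build_classifier(name: str, hyperparams: dict, seed: int):
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "linear_svm":
        return SVC(kernel="linear", C=hyperparams["C"], random_state=seed)
    if name == "logistic":
        return LogisticRegression(C=hyperparams["C"], max_iter=2000)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "neural_net":
        return MLPClassifier(
            hidden_layer_sizes=hyperparams["layers"],
            random_state=seed,
            max_iter=300,
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=hyperparams["n_estimators"], random_state=seed, n_jobs=1
        )
    if name == "rbf_svm":
        # gamma="auto" = 1 / (number of selected features)
        return SVC(kernel="rbf", C=hyperparams["C"], gamma="auto", random_state=seed)
    if name == "xgboost":
        return XGBClassifier(
            learning_rate=hyperparams["learning_rate"],
            n_estimators=hyperparams["n_estimators"],
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
        )
    raise ValueError(f"unknown classifier {name!r}")


def _continuous_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def run_cv(
    table: FeatureTable,
    config: ModelConfig,
    split: CVSplit,
    seed: int = 0,
    score_cache: dict | None = None,
) -> PooledPrediction:
    """Run one configuration through the shared CV split.

    Feature scoring and top-N selection use the nine training folds only
    (no leakage into the held-out fold); the classifier is then fitted on the
    selected columns and scores the held-out fold.

    Feature relevance depends only on the scoring method and the fold's
    training data — never on the classifier or N — so scorer child seeds
    derive from (seed, fs_method, fold) and a mutable ``score_cache`` dict
    (keyed by (fs_method, fold)) lets the study reuse one score vector across
    the whole classifier grid. Classifier child seeds derive from the full
    config key. A fixed master seed makes the run bit-reproducible either way.
    """
    scores = np.full(table.n_samples, np.nan)
    fold_selections: list[Selection] = []
    for fold in range(split.n_splits):
        train_idx = split.train_indices(fold)
        test_idx = split.test_indices(fold)
        cache_key = (config.fs_method, fold)
        if score_cache is not None and cache_key in score_cache:
            sv = score_cache[cache_key]
        else:
            sub = FeatureTable(
                table.values[train_idx],
                table.outcome[train_idx],
                table.feature_names,
                [table.sample_ids[i] for i in train_idx],
            )
            sv = score_features(
                sub, config.fs_method, seed=derive_seed(seed, config.fs_method, fold)
            )
            if score_cache is not None:
                score_cache[cache_key] = sv
        sel = select_top(sv, config.n_features)
        fold_selections.append(sel)
        fold_seed = derive_seed(seed, config.key(), fold)
        model = _build_classifier(config.classifier, config.hyperparam_dict, fold_seed)
        try:
            model.fit(
                table.values[np.ix_(train_idx, sel.indices)],
                table.outcome[train_idx],
            )
            scores[test_idx] = _continuous_scores(
                model, table.values[np.ix_(test_idx, sel.indices)]
            )
        except Exception as exc:  # noqa: BLE001 - annotate failing config/fold
            raise RuntimeError(
                f"classifier failed for config {config.key()} on fold {fold}: {exc}"
            ) from exc
    assert not np.isnan(scores).any()
    return PooledPrediction(scores, table.outcome.copy(), config, fold_selections)


def pooled_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of pooled out-of-fold scores; ties count 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("pooled AUC requires both classes")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def best_per_pair(
    results: list[tuple[ModelConfig, float]],
) -> dict[tuple[str, str], tuple[ModelConfig, float]]:
    """Best configuration per (fs_method, classifier) pair; first wins on ties.

    With the full grid this yields the 64 models that enter the equivalence
    analysis. Raises if any pair present in the grid axes is missing a result.
    """
    best: dict[tuple[str, str], tuple[ModelConfig, float]] = {}
    fs_seen, clf_seen = set(), set()
    for config, auc in results:
        fs_seen.add(config.fs_method)
        clf_seen.add(config.classifier)
        pair = (config.fs_method, config.classifier)
        if pair not in best or auc > best[pair][1]:
            best[pair] = (config, auc)
    missing = [
        pair for pair in product(sorted(fs_seen), sorted(clf_seen)) if pair not in best
    ]
    if missing:
        raise ValueError(f"results missing for pairs: {missing}")
    return best
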