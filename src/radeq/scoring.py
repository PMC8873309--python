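"""The eight feature-scoring methods and deterministic top-N selection.

Each scorer maps a preprocessed feature table to one relevance score per
feature (higher = more relevant); selection then takes the top N for
N in {1, 2, 4, 8, 16, 32, 64}. Four filters (ANOVA F, Bhattacharyya distance,
|Kendall tau-b|, binned mutual information) are seed-free and bit-
deterministic; FCBF and greedy mRMR-ensemble are implemented here in full;
LASSO and ExtraTrees wrap scikit-learn estimators.

Information-theoretic scores (MIM, FCBF) discretize continuous features into
ceil(sqrt(n)) equal-frequency bins and use plug-in entropies in nats — a
stated, reproducible estimator rather than a library-internal one.

Ties everywhere break by ascending feature index, so selections are
bit-reproducible, which the exact stability statistics rely on.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression

from .synthetic import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreVector",
    "Selection",
    "FS_METHODS",
    "N_FEATURES_GRID",
    "score_features",
    "score_anova",
    "score_bhattacharyya",
    "score_kendall",
    "score_mim",
    "score_fcbf",
    "score_lasso",
    "score_extratrees",
    "score_mrmre",
    "select_top",
]

FS_METHODS = (
    "anova",
    "bhattacharyya",
    "extratrees",
    "fcbf",
    "kendall",
    "lasso",
    "mim",
    "mrmre",
)
N_FEATURES_GRID = (1, 2, 4, 8, 16, 32, 64)

_VAR_FLOOR = 1e-12
_MRMR_MAX_SELECT = 64  # largest N the grid ever requests


@dataclass
class ScoreVector:
    method: str
    scores: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise ValueError(f"{self.method} produced non-finite scores")


@dataclass
class Selection:
    """Top-N selection: ordered indices plus a length-d indicator vector."""

    indices: np.ndarray
    indicator: np.ndarray
    n_requested: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.indicator = np.asarray(self.indicator, dtype=int)
        if self.indicator[self.indices].sum() != len(self.indices):
            raise ValueError("indicator inconsistent with indices")
        if self.indicator.sum() != len(self.indices):
            raise ValueError("indicator has extra selected features")


def _check_two_classes(outcome: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = outcome == 1
    neg = outcome == 0
    if not pos.any() or not neg.any():
        raise ValueError("both outcome classes must be present")
    return pos, neg


# --------------------------------------------------------------------------
# seed-free filters


def score_anova(table: FeatureTable) -> ScoreVector:
    """One-way ANOVA F statistic between the two outcome groups."""
    pos, neg = _check_two_classes(table.outcome)
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("ANOVA needs >= 2 samples per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = f_classif(table.values, table.outcome)
    return ScoreVector("anova", np.nan_to_num(f, nan=0.0, posinf=np.finfo(float).max))


def score_bhattacharyya(table: FeatureTable) -> ScoreVector:
    """Bhattacharyya distance between per-class univariate Gaussians.

    D = (mu1-mu0)^2 / (8*sbar^2) + 0.5*ln(sbar^2 / (s0*s1)), with
    sbar^2 = (s0^2 + s1^2)/2. Class variances below a small floor are floored
    (with a warning) so constant-within-class features stay finite.
    """
    pos, neg = _check_two_classes(table.outcome)
    x1, x0 = table.values[pos], table.values[neg]
    mu1, mu0 = x1.mean(axis=0), x0.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1) if x1.shape[0] > 1 else np.zeros(x1.shape[1])
    v0 = x0.var(axis=0, ddof=1) if x0.shape[0] > 1 else np.zeros(x0.shape[1])
    if (v1 < _VAR_FLOOR).any() or (v0 < _VAR_FLOOR).any():
        logger.warning("bhattacharyya: class variance below floor, flooring")
    v1 = np.maximum(v1, _VAR_FLOOR)
    v0 = np.maximum(v0, _VAR_FLOOR)
    vbar = 0.5 * (v0 + v1)
    d = (mu1 - mu0) ** 2 / (8.0 * vbar) + 0.5 * np.log(vbar / np.sqrt(v0 * v1))
    return ScoreVector("bhattacharyya", d)


def score_kendall(table: FeatureTable) -> ScoreVector:
    """|Kendall tau-b| of each feature against the binary outcome."""
    _check_two_classes(table.outcome)
    y = table.outcome
    scores = np.empty(table.n_features)
    for j in range(table.n_features):
        tau = stats.kendalltau(table.values[:, j], y).statistic
        scores[j] = 0.0 if math.isnan(tau) else abs(tau)
    return ScoreVector("kendall", scores)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into (up to) n_bins equal-frequency bins; returns int codes."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _entropy_from_codes(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_information(codes_x: np.ndarray, codes_y: np.ndarray) -> float:
    n = len(codes_x)
    xv, xi = np.unique(codes_x, return_inverse=True)
    yv, yi = np.unique(codes_y, return_inverse=True)
    joint = np.zeros((len(xv), len(yv)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())


def _binned(table: FeatureTable) -> np.ndarray:
    n_bins = int(math.ceil(math.sqrt(table.n_samples)))
    return np.column_stack(
        [_equal_frequency_bins(table.values[:, j], n_bins) for j in range(table.n_features)]
    )


def score_mim(table: FeatureTable) -> ScoreVector:
    """Plug-in mutual information of each (binned) feature with the outcome."""
    codes = _binned(table)
    y = table.outcome
    scores = np.array(
        [_mutual_information(codes[:, j], y) for j in range(table.n_features)]
    )
    return ScoreVector("mim", np.maximum(scores, 0.0))


def _symmetrical_uncertainty(cx: np.ndarray, cy: np.ndarray) -> float:
    hx, hy = _entropy_from_codes(cx), _entropy_from_codes(cy)
    if hx + hy == 0:
        return 0.0
    return 2.0 * _mutual_information(cx, cy) / (hx + hy)


def score_fcbf(table: FeatureTable) -> ScoreVector:
    """Fast correlation-based filter, expressed as a full ranking.

    Features are ranked by symmetrical uncertainty SU(x, y) with the outcome;
    the classic predominant-correlate rule then eliminates any feature whose
    SU with an already-kept, more relevant feature is at least its SU with the
    outcome. Kept features score their SU; eliminated features score strictly
    below every kept feature (still ordered among themselves by SU), so top-N
    selection prefers the non-redundant set but degrades gracefully when N
    exceeds it.
    """
    codes = _binned(table)
    y = table.outcome
    d = table.n_features
    su_y = np.array([_symmetrical_uncertainty(codes[:, j], y) for j in range(d)])
    order = np.argsort(-su_y, kind="stable")  # ties -> ascending index
    alive = np.ones(d, dtype=bool)
    kept: list[int] = []
    for pos, j in enumerate(order):
        if not alive[j]:
            continue
        kept.append(j)
        for k in order[pos + 1 :]:
            if alive[k] and _symmetrical_uncertainty(codes[:, j], codes[:, k]) >= su_y[k]:
                alive[k] = False
    scores = su_y.copy()
    removed = ~alive
    scores[removed] = su_y[removed] - 2.0  # SU in [0,1] => strictly below survivors
    return ScoreVector("fcbf", scores)


# --------------------------------------------------------------------------
# wrappers


def score_lasso(table: FeatureTable, max_iter: int = 2000) -> ScoreVector:
    """|coefficients| of an L1-penalized logistic model at fixed C = 1.0."""
    _check_two_classes(table.outcome)
    model = LogisticRegression(
        l1_ratio=1, C=1.0, solver="liblinear", max_iter=max_iter
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(table.values, table.outcome)
        except ConvergenceWarning:
            model.set_params(max_iter=max_iter * 10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(table.values, table.outcome)
    return ScoreVector("lasso", np.abs(model.coef_.ravel()))


def score_extratrees(table: FeatureTable, seed: int = 0) -> ScoreVector:
    """Impurity importances of an extremely-randomized-trees ensemble."""
    _check_two_classes(table.outcome)
    model = ExtraTreesClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    model.fit(table.values, table.outcome)
    return ScoreVector("extratrees", model.feature_importances_, seed=seed)


def _abs_pearson_with(values: np.ndarray, target: np.ndarray) -> np.ndarray:
    """|Pearson r| of each column with a target; constant columns score 0."""
    xc = values - values.mean(axis=0)
    tc = target - target.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    st = math.sqrt((tc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * tc[:, None]).sum(axis=0) / (sx * st)
    return np.abs(np.nan_to_num(r, nan=0.0))


def _greedy_mrmr(values: np.ndarray, outcome: np.ndarray, n_select: int) -> list[int]:
    """Greedy mRMR: maximize |r(x, y)| minus mean |r| with already-selected."""
    d = values.shape[1]
    relevance = _abs_pearson_with(values, outcome.astype(float))
    selected: list[int] = [int(np.argmax(relevance))]
    redundancy_sum = np.zeros(d)
    candidates = np.ones(d, dtype=bool)
    candidates[selected[0]] = False
    while len(selected) < min(n_select, d):
        last = values[:, selected[-1]]
        redundancy_sum += _abs_pearson_with(values, last)
        objective = relevance - redundancy_sum / len(selected)
        objective[~candidates] = -np.inf
        nxt = int(np.argmax(objective))  # argmax ties -> lowest index
        selected.append(nxt)
        candidates[nxt] = False
    return selected


def score_mrmre(table: FeatureTable, n_ensembles: int = 5, seed: int = 0) -> ScoreVector:
    """Ensemble mRMR: aggregate greedy selection ranks over bootstrap runs.

    Each of ``n_ensembles`` members runs greedy mRMR (correlation-based
    relevance minus mean redundancy) on a bootstrap resample of the rows,
    selecting up to 64 features. A feature's score is its mean inverse
    selection rank across members (unselected contributes 0), so earlier,
    more consistent picks score higher. Deterministic given the seed.
    """
    if table.n_features < 2:
        raise ValueError("mrmre requires at least 2 features")
    rng = np.random.default_rng(seed)
    n = table.n_samples
    scores = np.zeros(table.n_features)
    for _ in range(n_ensembles):
        rows = rng.integers(0, n, size=n)
        # resample until both classes present (guaranteed to terminate)
        while len(np.unique(table.outcome[rows])) < 2:
            rows = rng.integers(0, n, size=n)
        picks = _greedy_mrmr(table.values[rows], table.outcome[rows], _MRMR_MAX_SELECT)
        for rank, j in enumerate(picks, start=1):
            scores[j] += 1.0 / rank
    return ScoreVector("mrmre", scores / n_ensembles, seed=seed)


# --------------------------------------------------------------------------
# dispatch and selection

_SCORERS_SEEDED = {"extratrees": score_extratrees, "mrmre": score_mrmre}
_SCORERS_PLAIN = {
    "anova": score_anova,
    "bhattacharyya": score_bhattacharyya,
    "kendall": score_kendall,
    "mim": score_mim,
    "fcbf": score_fcbf,
    "lasso": score_lasso,
}


def score_features(table: FeatureTable, method: str, seed: int = 0) -> ScoreVector:
    """Score all features with one of the eight methods."""
    if method in _SCORERS_PLAIN:
        return _SCORERS_PLAIN[method](table)
    if method in _SCORERS_SEEDED:
        return _SCORERS_SEEDED[method](table, seed=seed)
    raise ValueError(f"unknown scoring method {method!r}; choose from {FS_METHODS}")


def select_top(scores: ScoreVector, n_requested: int) -> Selection:
    """Pick the min(N, d) highest-scoring features; ties break by low index."""
    if n_requested not in N_FEATURES_GRID:
        raise ValueError(
            f"n_requested must be one of {N_FEATURES_GRID}, got {n_requested}"
        )
    d = len(scores.scores)
    n_take = min(n_requested, d)
    order = np.argsort(-scores.scores, kind="stable")
    indices = np.sort(order[:n_take])
    indicator = np.zeros(d, dtype=int)
    indicator[indices] = 1
    return Selection(indices, indicator, n_requested)
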