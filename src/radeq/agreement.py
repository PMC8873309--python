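"""Selection-agreement statistics: stability, similarity, and the
correlation-aware feature-set concordance, plus the all-pairs
feature-correlation histogram.

All three statistics operate on the binary per-fold selection indicator
vectors a model's CV run produces:

* **stability** of one model — mean Pearson correlation of its indicator
  vectors over all 45 unordered fold pairs; exactly 1.0 iff every fold
  selects the identical set.
* **similarity** between two models — mean Pearson correlation of the two
  models' indicator vectors on matched folds (same training data), averaged
  over the 10 folds. A ``pairing="cross"`` mode averages over all ordered
  fold pairs instead, under which similarity(A, A) equals stability(A)
  exactly.
* **feature-set correlation** — similarity is blind to the heavy feature
  correlation of radiomic tables, where two models can select different but
  nearly interchangeable features. Per fold, each feature selected by model A
  is matched to its highest |Pearson r| partner (computed on the full
  preprocessed table) among model B's selections; those maxima are averaged
  over A's features, the two directions are averaged, then folds are
  averaged. Exactly 1.0 when every selected feature has a perfectly
  (anti-)correlated counterpart on the other side.

Pearson correlation is undefined on constant indicator vectors (empty or
all-selected folds); such a pair contributes 1 if the two vectors are
identical — preserving the identical-sets-give-1.0 boundary — and 0
otherwise, with a warning.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np

from .delong import EquivalenceSet
from .harness import ModelConfig
from .scoring import Selection
from .synthetic import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "stability",
    "similarity",
    "feature_set_correlation",
    "correlation_histogram",
    "summarize_equivalence",
]


def _indicator_corr(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson r of two binary indicator vectors, with the constant-vector rule."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.array_equal(u, v):
        return 1.0  # identical sets: exact boundary value, constants included
    su, sv = u.std(), v.std()
    if su == 0.0 or sv == 0.0:
        logger.warning("constant selection indicator encountered; pair scored 0")
        return 0.0
    r = ((u - u.mean()) * (v - v.mean())).mean() / (su * sv)
    return float(np.clip(r, -1.0, 1.0))


def _indicators(selections: list[Selection], d: int) -> np.ndarray:
    mat = np.zeros((len(selections), d))
    for i, sel in enumerate(selections):
        if len(sel.indicator) != d:
            raise ValueError("selection indicator length does not match d")
        mat[i] = sel.indicator
    return mat


def stability(fold_selections: list[Selection], d: int) -> float:
    """Mean Pearson correlation of fold indicators over unordered fold pairs."""
    mat = _indicators(fold_selections, d)
    pairs = list(combinations(range(len(fold_selections)), 2))
    if not pairs:
        raise ValueError("stability needs at least two folds")
    return float(np.mean([_indicator_corr(mat[i], mat[j]) for i, j in pairs]))


def similarity(
    selections_a: list[Selection],
    selections_b: list[Selection],
    d: int,
    pairing: str = "matched",
) -> float:
    """Mean Pearson correlation between two models' fold indicators.

    ``pairing="matched"`` (default) correlates fold i of A with fold i of B —
    both models ran on the same CV split, so matched folds saw the same
    training data. ``pairing="cross"`` averages over all ordered pairs of
    distinct folds; with A = B this reproduces stability exactly.
    """
    if len(selections_a) != len(selections_b):
        raise ValueError("both models must have the same number of folds")
    mat_a = _indicators(selections_a, d)
    mat_b = _indicators(selections_b, d)
    k = len(selections_a)
    if pairing == "matched":
        return float(np.mean([_indicator_corr(mat_a[i], mat_b[i]) for i in range(k)]))
    if pairing == "cross":
        vals = [
            _indicator_corr(mat_a[i], mat_b[j])
            for i in range(k)
            for j in range(k)
            if i != j
        ]
        return float(np.mean(vals))
    raise ValueError("pairing must be 'matched' or 'cross'")


def feature_set_correlation(
    table: FeatureTable,
    selections_a: list[Selection],
    selections_b: list[Selection],
) -> float:
    """Average best-match |Pearson r| between two models' selected features.

    Correlations are taken on the full (preprocessed) table; the statistic is
    symmetrized over the two directions and averaged over folds; lies in
    [0, 1], reaching 1 only if every selected feature on each side has a
    perfectly correlated partner on the other.
    """
    if len(selections_a) != len(selections_b):
        raise ValueError("both models must have the same number of folds")
    corr = np.abs(np.corrcoef(table.values, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    per_fold = []
    for sel_a, sel_b in zip(selections_a, selections_b):
        ia, ib = sel_a.indices, sel_b.indices
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError("feature_set_correlation requires nonempty selections")
        a_to_b = corr[np.ix_(ia, ib)].max(axis=1).mean()
        b_to_a = corr[np.ix_(ib, ia)].max(axis=1).mean()
        per_fold.append(0.5 * (a_to_b + b_to_a))
    return float(np.clip(np.mean(per_fold), 0.0, 1.0))


def correlation_histogram(
    table: FeatureTable,
    n_bins: int = 100,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of Pearson r over all d(d-1)/2 unordered feature pairs.

    Independent-Gaussian tables concentrate near 0; correlated-block tables
    show the characteristic fat right tail. For very wide tables the pair set
    is subsampled uniformly at random (seeded) to bound cost.
    """
    d = table.n_features
    if d < 2:
        raise ValueError("need at least 2 features")
    corr = np.corrcoef(table.values, rowvar=False)
    iu = np.triu_indices(d, k=1)
    r = corr[iu]
    n_pairs = len(r)
    if n_pairs > max_pairs:
        rng = np.random.default_rng(seed)
        r = rng.choice(r, size=max_pairs, replace=False)
        logger.warning("correlation_histogram: subsampled %d of %d pairs", max_pairs, n_pairs)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, edges = np.histogram(r, bins=edges)
    return edges, counts


def summarize_equivalence(
    eq_set: EquivalenceSet,
    fold_selections: dict[str, list[Selection]],
    table: FeatureTable,
) -> dict:
    """Agreement summary over the best model and its equivalence set.

    ``fold_selections`` maps config keys to the per-fold selections recorded
    during CV. Returns mean stability over {best} ∪ members, and mean
    similarity / feature-set correlation of each member against the best,
    each with its (min, max) range.
    """
    d = table.n_features
    best_key = eq_set.best.key()
    best_sel = fold_selections[best_key]
    member_configs: list[ModelConfig] = [cfg for cfg, _ in eq_set.members]

    stab = [stability(best_sel, d)] + [
        stability(fold_selections[cfg.key()], d) for cfg in member_configs
    ]
    sims = [
        similarity(fold_selections[cfg.key()], best_sel, d) for cfg in member_configs
    ]
    corrs = [
        feature_set_correlation(table, fold_selections[cfg.key()], best_sel)
        for cfg in member_configs
    ]

    def _summ(vals: list[float]) -> dict:
        if not vals:
            return {"mean": float("nan"), "min": float("nan"), "max": float("nan")}
        return {
            "mean": float(np.mean(vals)),
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
        }

    return {
        "stability": _summ(stab),
        "similarity": _summ(sims),
        "correlation": _summ(corrs),
    }
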