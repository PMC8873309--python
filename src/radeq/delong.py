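"""Paired DeLong comparison of correlated AUCs, from structural components.

Two models scored the same pooled cross-validation samples, so their AUCs are
correlated; the DeLong construction estimates that correlation from
per-sample placement ("structural") components and tests the AUC difference
with an asymptotic normal z. Midranks are used throughout so heavily tied
score vectors (tree ensembles, pooled CV) are handled exactly as in the
reference formulation.

For an event sample i, the placement V10_i is the fraction of non-events it
outranks (ties half); for a non-event j, V01_j is the fraction of events it
is outranked by (ties half). The AUC is the mean placement on either side,
and for two models a and b the variance of auc_a - auc_b is

    var = (S10[aa] + S10[bb] - 2 S10[ab]) / m + (S01[aa] + S01[bb] - 2 S01[ab]) / n

with S10 / S01 the sample covariance matrices of the event / non-event
placements and m / n the class counts.

The comparison against a constant model (every sample scored 0.5) reduces to
a one-sample test of AUC = 0.5: the constant comparator's placements have
zero variance, so only the real model's variance enters.

An equivalence set collects, for 64 best-per-pair models, those whose pooled
AUC cannot be shown to differ from the overall best model's at alpha = 0.05,
with no multiple-testing adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .harness import ModelConfig, PooledPrediction, pooled_auc

__all__ = [
    "DeLongResult",
    "EquivalenceSet",
    "DegenerateVarianceError",
    "placements",
    "delong_paired",
    "compare_to_constant",
    "equivalence_set",
]

_AUC_TIE_TOL = 1e-12


class DegenerateVarianceError(RuntimeError):
    """var(auc_a - auc_b) = 0 while the AUCs differ: a pathological fixture."""


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float


@dataclass
class EquivalenceSet:
    """The best model plus every model not shown to differ from it."""

    best: ModelConfig
    best_auc: float
    members: list[tuple[ModelConfig, float]]  # (config, p_value), p >= alpha
    alpha: float = 0.05
    p_values: dict[str, float] = field(default_factory=dict)  # config key -> p


def placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midrank placement components (V10 per event, V01 per non-event).

    mean(V10) = mean(V01) = the Mann-Whitney AUC with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def _cov(u: np.ndarray, v: np.ndarray) -> float:
    if len(u) < 2:
        return 0.0
    return float(((u - u.mean()) * (v - v.mean())).sum() / (len(u) - 1))


def delong_paired(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> DeLongResult:
    """Two-sided paired DeLong test of AUC_a = AUC_b on shared labels."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    v10_a, v01_a = placements(scores_a, labels)
    v10_b, v01_b = placements(scores_b, labels)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    m, n = len(v10_a), len(v01_a)
    var_diff = (
        _cov(v10_a, v10_a) + _cov(v10_b, v10_b) - 2 * _cov(v10_a, v10_b)
    ) / m + (_cov(v01_a, v01_a) + _cov(v01_b, v01_b) - 2 * _cov(v01_a, v01_b)) / n
    var_diff = max(var_diff, 0.0)
    if var_diff == 0.0:
        if abs(auc_a - auc_b) <= _AUC_TIE_TOL:
            return DeLongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise DegenerateVarianceError(
            f"zero variance of the AUC difference with unequal AUCs "
            f"({auc_a:.6f} vs {auc_b:.6f})"
        )
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, float(var_diff), float(z), p)


def compare_to_constant(scores: np.ndarray, labels: np.ndarray) -> DeLongResult:
    """One-sample DeLong test of a model's AUC against the constant model.

    The constant comparator scores every sample 0.5, so its AUC is exactly
    0.5 with zero-variance placements; the test statistic uses only the real
    model's placement variance. Zero variance arises in two opposite
    regimes: all-tied scores (AUC 0.5, no evidence, p = 1) and perfect
    separation (every placement exactly 0 or 1, the strongest possible
    evidence, p = 0).
    """
    v10, v01 = placements(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = _cov(v10, v10) / m + _cov(v01, v01) / n
    if var <= 0.0:
        if abs(auc - 0.5) <= _AUC_TIE_TOL:
            return DeLongResult(auc, 0.5, 0.0, 0.0, 1.0)
        z = math.copysign(math.inf, auc - 0.5)
        return DeLongResult(auc, 0.5, 0.0, z, 0.0)
    z = (auc - 0.5) / np.sqrt(var)
    return DeLongResult(auc, 0.5, float(var), float(z), float(2.0 * norm.sf(abs(z))))


def equivalence_set(
    predictions: list[PooledPrediction], alpha: float = 0.05
) -> EquivalenceSet:
    """Best model (highest pooled AUC, ties by order) and its equivalence set.

    Every other model is compared to the best with the paired DeLong test;
    members are those with p >= alpha. No multiplicity adjustment.
    """
    if not predictions:
        raise ValueError("no predictions given")
    labels = predictions[0].labels
    for pred in predictions[1:]:
        if not np.array_equal(pred.labels, labels):
            raise ValueError("all predictions must share one label vector")
    aucs = [pooled_auc(p.scores, p.labels) for p in predictions]
    best_i = int(np.argmax(aucs))  # first max wins
    best = predictions[best_i]
    members: list[tuple[ModelConfig, float]] = []
    p_values: dict[str, float] = {}
    for i, pred in enumerate(predictions):
        if i == best_i:
            continue
        res = delong_paired(pred.scores, best.scores, labels)
        p_values[pred.config.key()] = res.p_value
        if res.p_value >= alpha:
            members.append((pred.config, res.p_value))
    return EquivalenceSet(best.config, float(aucs[best_i]), members, alpha, p_values)
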