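"""The eight scoring methods against hand and brute-force oracles."""

import math
from itertools import combinations

import numpy as np
import pytest

from radeq import score_features, select_top
from radeq.scoring import (
    FS_METHODS,
    ScoreVector,
    score_anova,
    score_bhattacharyya,
    score_extratrees,
    score_fcbf,
    score_kendall,
    score_lasso,
    score_mim,
    score_mrmre,
)

from conftest import make_table


def _entropy(labels):
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _brute_force_tau_b(x, y):
    """Exhaustive concordant/discordant pair count with tie correction."""
    n = len(x)
    nc = nd = tx = ty = 0
    for i, j in combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            nc += 1
        else:
            nd += 1
    n0 = n * (n - 1) / 2
    return (nc - nd) / math.sqrt((n0 - tx) * (n0 - ty))


class TestAnova:
    def test_hand_computed_f(self):
        # class 0: [0,1], class 1: [4,5] -> SSB/dfB / (SSW/dfW) = 16/0.5 = 32
        t = make_table([[0.0], [1.0], [4.0], [5.0]], [0, 0, 1, 1])
        assert score_anova(t).scores[0] == pytest.approx(32.0)

    def test_identical_classes_give_zero(self):
        t = make_table([[1.0], [2.0], [1.0], [2.0]], [0, 0, 1, 1])
        assert score_anova(t).scores[0] == pytest.approx(0.0)

    def test_requires_two_per_class(self):
        t = make_table([[1.0], [2.0], [3.0]], [0, 0, 1])
        with pytest.raises(ValueError):
            score_anova(t)


class TestBhattacharyya:
    def test_equal_distributions_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        t = make_table(np.concatenate([x, x])[:, None], [0] * 40 + [1] * 40)
        assert score_bhattacharyya(t).scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_unit_variance_shift(self):
        # mu0=0, mu1=2, sigma0=sigma1=1 -> D = (2^2)/8 = 0.5
        rng = np.random.default_rng(1)
        x0 = rng.normal(size=5000)
        x0 = (x0 - x0.mean()) / x0.std(ddof=1)
        t = make_table(np.concatenate([x0, x0 + 2.0])[:, None], [0] * 5000 + [1] * 5000)
        assert score_bhattacharyya(t).scores[0] == pytest.approx(0.5, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = np.repeat([0, 1], 30)
        x[y == 1] += 1.0
        d1 = score_bhattacharyya(make_table(x[:, None], y)).scores[0]
        d2 = score_bhattacharyya(make_table(7.5 * x[:, None], y)).scores[0]
        assert d1 == pytest.approx(d2, rel=1e-10)


class TestKendall:
    def test_matches_brute_force_pair_count(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 0, 1, 1])
        t = make_table(x[:, None], y)
        assert score_kendall(t).scores[0] == pytest.approx(
            abs(_brute_force_tau_b(x, y)), abs=1e-12
        )

    def test_perfect_ordering_attains_tie_corrected_maximum(self):
        # with a binary outcome the tie correction caps tau-b below 1:
        # strict separation gives nc = m*n, nd = 0 -> tau = sqrt(mn / C(n,2))
        y = np.repeat([0, 1], 20)
        x = np.arange(40.0)
        t = make_table(x[:, None], y)
        tau = score_kendall(t).scores[0]
        assert tau == pytest.approx(abs(_brute_force_tau_b(x, y)), abs=1e-12)
        assert tau == pytest.approx(math.sqrt(20 * 20 / (40 * 39 / 2)), abs=1e-12)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.normal(size=(500, 1)), rng.integers(0, 2, 500))
        assert score_kendall(t).scores[0] < 0.1


class TestMutualInformation:
    def test_feature_equal_to_outcome_recovers_entropy(self):
        y = np.array([0] * 30 + [1] * 20)
        t = make_table(y.astype(float)[:, None], y)
        assert score_mim(t).scores[0] == pytest.approx(_entropy(y), abs=1e-12)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(4)
        t = make_table(rng.normal(size=(1000, 1)), rng.integers(0, 2, 1000))
        assert score_mim(t).scores[0] < 0.03

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        t = make_table(rng.normal(size=(50, 3)), rng.integers(0, 2, 50))
        np.testing.assert_array_equal(score_mim(t).scores, score_mim(t).scores)


class TestFCBF:
    def test_duplicate_feature_is_eliminated(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 20)
        x0 = y + 0.05 * rng.normal(size=40)
        noise = rng.normal(size=40)
        t = make_table(np.column_stack([x0, x0, noise]), y)
        scores = score_fcbf(t).scores
        assert scores[0] >= 0.0  # survivor keeps its SU
        assert scores[1] < 0.0  # exact duplicate removed by redundancy rule
        survivors = scores[scores >= 0.0]
        assert scores[1] < survivors.min()  # strictly below all survivors

    def test_independent_features_rank_by_su(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 50)
        strong = y + 0.2 * rng.normal(size=100)
        weak = y + 2.0 * rng.normal(size=100)
        t = make_table(np.column_stack([weak, strong]), y)
        scores = score_fcbf(t).scores
        assert scores[1] > scores[0]

    def test_su_bounds(self):
        rng = np.random.default_rng(8)
        t = make_table(rng.normal(size=(60, 5)), rng.integers(0, 2, 60))
        scores = score_fcbf(t).scores
        # survivors carry SU in [0, 1]; eliminated features sit 2 below
        assert ((scores <= 1.0) & (scores >= -2.0)).all()


class TestLasso:
    def test_informative_feature_gets_largest_coefficient(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 50)
        x = rng.normal(size=(100, 10))
        x[:, 4] += 2.0 * y
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        t = make_table(x, y)
        assert int(np.argmax(score_lasso(t).scores)) == 4

    def test_all_zero_coefficients_still_selectable(self):
        rng = np.random.default_rng(10)
        t = make_table(0.001 * rng.normal(size=(30, 4)), np.repeat([0, 1], 15))
        sv = score_lasso(t)
        sel = select_top(sv, 2)
        assert len(sel.indices) == 2  # tie-broken deterministically


class TestExtraTrees:
    def test_seed_determinism_and_normalization(self, block_table):
        a = score_extratrees(block_table, seed=3)
        b = score_extratrees(block_table, seed=3)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.scores.sum() == pytest.approx(1.0, abs=1e-6)
        assert (a.scores >= 0).all()

    def test_strong_feature_tops_importances_across_seeds(self):
        rng = np.random.default_rng(11)
        y = np.repeat([0, 1], 50)
        x = rng.normal(size=(100, 20))
        x[:, 13] += 3.0 * y
        t = make_table(x, y)
        hits = sum(
            int(np.argmax(score_extratrees(t, seed=s).scores) == 13) for s in range(20)
        )
        assert hits >= 19  # >= 95% of seeds


class TestMRMRe:
    def test_redundant_copy_ranks_below_independent_feature(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1], 40)
        x0 = y + 0.3 * rng.normal(size=80)
        x2 = y + 0.6 * rng.normal(size=80)
        t = make_table(np.column_stack([x0, x0, x2]), y)
        scores = score_mrmre(t, seed=0).scores
        # x0 always wins the tie with its copy; the copy pays full redundancy
        assert scores[0] > scores[2] > scores[1]

    def test_independent_features_follow_relevance(self):
        rng = np.random.default_rng(13)
        y = np.repeat([0, 1], 60)
        x = np.column_stack(
            [y + s * rng.normal(size=120) for s in (0.3, 3.0, 0.8)]
        )
        t = make_table(x, y)
        scores = score_mrmre(t, seed=1).scores
        assert int(np.argmax(scores)) == 0  # strongest relevance picked first

    def test_seed_determinism(self, block_table):
        a = score_mrmre(block_table, seed=5).scores
        b = score_mrmre(block_table, seed=5).scores
        np.testing.assert_array_equal(a, b)


class TestSelectTop:
    def test_tie_broken_by_ascending_index(self):
        sv = ScoreVector("anova", np.array([0.9, 0.1, 0.9]))
        sel = select_top(sv, 2)
        assert set(sel.indices.tolist()) == {0, 2}

    def test_single_best(self):
        sv = ScoreVector("anova", np.array([0.2, 0.7, 0.5]))
        assert select_top(sv, 1).indices.tolist() == [1]

    def test_caps_at_d(self):
        sv = ScoreVector("anova", np.arange(3.0))
        sel = select_top(sv, 64)
        assert len(sel.indices) == 3
        assert sel.indicator.sum() == 3

    def test_rejects_off_grid_n(self):
        sv = ScoreVector("anova", np.arange(3.0))
        with pytest.raises(ValueError):
            select_top(sv, 3)


@pytest.mark.parametrize("method", ["anova", "bhattacharyya", "kendall", "mim", "fcbf"])
def test_filter_methods_invariant_to_row_and_column_permutation(method):
    rng = np.random.default_rng(14)
    values = rng.normal(size=(60, 6))
    outcome = np.repeat([0, 1], 30)
    values[:, 2] += outcome
    t = make_table(values, outcome)
    base = score_features(t, method).scores

    rperm = rng.permutation(60)
    t_rows = make_table(values[rperm], outcome[rperm])
    np.testing.assert_allclose(score_features(t_rows, method).scores, base, atol=1e-12)

    cperm = rng.permutation(6)
    t_cols = make_table(values[:, cperm], outcome)
    np.testing.assert_allclose(
        score_features(t_cols, method).scores, base[cperm], atol=1e-12
    )


@pytest.mark.parametrize("method", FS_METHODS)
def test_every_method_returns_finite_scores(method, block_table):
    sv = score_features(block_table, method, seed=0)
    assert sv.scores.shape == (block_table.n_features,)
    assert np.isfinite(sv.scores).all()
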