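"""Rank tests, correlation, BH and ROC against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pancankit import stats


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------

def mann_whitney_exact_oracle(x, y):
    """Two-sided p by full enumeration of all C(n, nx) rank labelings."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    obs = ranks[:nx].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, nx)]
    total = len(sums)
    p_le = sum(s <= obs + 1e-9 for s in sums) / total
    p_ge = sum(s >= obs - 1e-9 for s in sums) / total
    return min(1.0, 2 * min(p_le, p_ge))


def signed_rank_exact_oracle(d):
    """Two-sided p over all 2^n sign assignments of |d| ranks."""
    d = np.asarray(d, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    obs = ranks[d > 0].sum()
    n = len(d)
    stats_all = [sum(r for r, s in zip(ranks, signs) if s)
                 for signs in itertools.product([False, True], repeat=n)]
    total = len(stats_all)
    p_le = sum(s <= obs + 1e-9 for s in stats_all) / total
    p_ge = sum(s >= obs - 1e-9 for s in stats_all) / total
    return min(1.0, 2 * min(p_le, p_ge))


def test_mann_whitney_separated_groups_exact():
    res = stats.mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p == pytest.approx(2 / 20, abs=1e-12)


def test_mann_whitney_exchangeable_groups():
    assert stats.mann_whitney([1, 2], [1, 2]).p == 1.0


def test_mann_whitney_group_size_guard():
    with pytest.raises(ValueError):
        stats.mann_whitney([1.0], [2.0, 3.0])


@pytest.mark.parametrize("seed", range(12))
def test_mann_whitney_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    nx, ny = rng.integers(2, 7, size=2)
    pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
    x, y = pooled[:nx], pooled[nx:]
    res = stats.mann_whitney(x, y)
    assert res.p == pytest.approx(mann_whitney_exact_oracle(x, y), abs=1e-10)


def test_mann_whitney_exact_close_to_normal_approximation():
    """At n=8/8 the exact p and an independent asymptotic p agree to 0.01."""
    from scipy.stats import mannwhitneyu
    rng = np.random.default_rng(42)
    gaps = []
    for _ in range(500):
        pooled = rng.permutation(np.arange(1.0, 17))
        x, y = pooled[:8], pooled[8:]
        exact = stats.mann_whitney(x, y).p  # exact branch (min n = 8, no ties)
        approx = mannwhitneyu(x, y, method="asymptotic",
                              use_continuity=True).pvalue
        gaps.append(abs(approx - exact))
    # the continuity-corrected normal approximation sits within ~0.011
    # of the enumerated null at worst at this sample size
    assert max(gaps) < 0.011


def test_signed_rank_all_positive():
    res = stats.wilcoxon_signed_rank([1, 2, 3])
    assert res.statistic == 6.0
    assert res.p == pytest.approx(2 / 8, abs=1e-12)


def test_signed_rank_two_pairs():
    assert stats.wilcoxon_signed_rank([-1, 2]).p == 1.0


def test_signed_rank_degenerate():
    with pytest.raises(ValueError):
        stats.wilcoxon_signed_rank([0, 0])


@pytest.mark.parametrize("seed", range(10))
def test_signed_rank_matches_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(3, 10))
    d = rng.permutation(np.arange(1.0, n + 1)) * rng.choice([-1, 1], n)
    res = stats.wilcoxon_signed_rank(d)
    assert res.p == pytest.approx(signed_rank_exact_oracle(d), abs=1e-10)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_pearson_perfect_line():
    assert stats.correlation([1, 2, 3], [2, 4, 6]).effect == 1.0


def test_pearson_hand_computed():
    # cov = 1.25, sd product = 1.25 * (5/4): r = 4/5
    assert stats.correlation([1, 2, 3, 4], [1, 3, 2, 4]).effect == \
        pytest.approx(0.8, abs=1e-12)


def test_spearman_monotone_invariance():
    x = np.array([0.3, 1.2, 2.9, 4.1, 7.7])
    assert stats.correlation(x, np.exp(x), "spearman").effect == 1.0


def test_correlation_constant_errors():
    with pytest.raises(ValueError):
        stats.correlation([1, 1, 1], [1, 2, 3])


def test_correlation_p_matches_scipy():
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=30), rng.normal(size=30)
    from scipy.stats import pearsonr, spearmanr
    ours = stats.correlation(x, y)
    ref = pearsonr(x, y)
    assert ours.effect == pytest.approx(ref.statistic, abs=1e-12)
    assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
    ours_s = stats.correlation(x, y, "spearman")
    assert ours_s.effect == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kruskal_identical_groups():
    res = stats.kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == 1.0


def test_kruskal_brute_force_formula():
    groups = [[1, 2], [3, 4], [5, 6]]
    # ranks are the values themselves: H = 12/(6*7) * sum(R^2/2) - 3*7
    h = 12 / 42 * ((1 + 2) ** 2 / 2 + (3 + 4) ** 2 / 2 + (5 + 6) ** 2 / 2) - 21
    res = stats.kruskal_wallis(groups)
    assert res.statistic == pytest.approx(h, abs=1e-10)


def test_kruskal_shift_invariance():
    groups = [[1.0, 5.0], [2.0, 7.5], [3.3, 4.4]]
    shifted = [[v + 11.7 for v in g] for g in groups]
    assert stats.kruskal_wallis(groups).statistic == \
        pytest.approx(stats.kruskal_wallis(shifted).statistic, abs=1e-12)


def test_kruskal_needs_three_groups():
    with pytest.raises(ValueError, match="mann_whitney"):
        stats.kruskal_wallis([[1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# BH and stars
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pvals,expected", [
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([0.05], [0.05]),
    ([0.01, 1.0], [0.02, 1.0]),
])
def test_bh_hand_computed(pvals, expected):
    np.testing.assert_allclose(stats.benjamini_hochberg(pvals), expected,
                               atol=1e-12)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
       st.randoms(use_true_random=False))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_bh_permutation_equivariance(pvals, rnd):
    perm = list(range(len(pvals)))
    rnd.shuffle(perm)
    q = stats.benjamini_hochberg(pvals)
    q_perm = stats.benjamini_hochberg([pvals[i] for i in perm])
    np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)
    assert np.all(q >= np.asarray(pvals) - 1e-12)
    assert np.all(q <= 1.0)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        stats.benjamini_hochberg([0.5, 1.5])


@pytest.mark.parametrize("p,label", [
    (0.03, "*"), (0.2, "ns"), (0.0005, "***"), (0.05, "ns"),
    (0.009, "**"), (5e-5, "****"), (0.0, "****"), (1.0, "ns"),
])
def test_significance_stars(p, label):
    assert stats.significance_stars(p) == label


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_roc_perfect_separation():
    res = stats.roc_auc([5, 6, 7, 1, 2], [1, 1, 1, 0, 0])
    assert res.auc == 1.0


def test_roc_all_ties():
    assert stats.roc_auc([3, 3, 3, 3], [1, 0, 1, 0]).auc == 0.5


def test_roc_concordant_pairs():
    res = stats.roc_auc([2, 4, 1, 3], [1, 1, 0, 0])
    assert res.auc == pytest.approx(3 / 4, abs=1e-12)


def test_roc_one_class_errors():
    with pytest.raises(ValueError):
        stats.roc_auc([1, 2, 3], [1, 1, 1])


@pytest.mark.parametrize("seed", range(20))
def test_roc_mann_whitney_identity(seed):
    """Trapezoid AUC equals the midrank U/(n1*n0) identity, ties included."""
    rng = np.random.default_rng(seed)
    n1, n0 = rng.integers(3, 30, size=2)
    scores = np.r_[rng.integers(0, 8, n1), rng.integers(0, 8, n0)].astype(float)
    labels = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
    res = stats.roc_auc(scores, labels)
    u = stats.mann_whitney(scores[labels], scores[~labels]).statistic
    assert res.auc == pytest.approx(u / (n1 * n0), abs=1e-12)
    assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
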