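"""Statistical tests checked against independent enumeration oracles."""

import itertools
from math import comb

import numpy as np
import pytest
import scipy.stats as sps

from ocuscan.stats import (
    Contingency2x2,
    PairedComparison,
    bws_test,
    corrected_resampled_ttest,
    fisher_exact,
    mann_whitney,
    permutation_pvalue,
    sign_test,
)


# ---------------------------------------------------------------------------
# Sign test


def sign_test_oracle(wins, losses):
    """Exhaustive enumeration over all 2^n win/loss patterns."""
    n = wins + losses
    hits = sum(1 for pat in itertools.product([0, 1], repeat=n) if sum(pat) >= wins)
    return hits / 2**n


@pytest.mark.parametrize("wins,losses", [(0, 5), (3, 2), (7, 0), (6, 6), (1, 11), (12, 0)])
def test_sign_test_matches_exhaustive_enumeration(wins, losses):
    p = sign_test(PairedComparison(wins, losses)).p
    assert p == pytest.approx(sign_test_oracle(wins, losses), rel=1e-12)


def test_sign_test_threshold_semantics():
    """50/50 wins is the only 50-run outcome at or below 1e-15."""
    p50 = sign_test(PairedComparison(50, 0)).p
    assert p50 == pytest.approx(2.0**-50, rel=1e-9)
    assert p50 <= 1e-15
    p49 = sign_test(PairedComparison(49, 1)).p
    assert p49 == pytest.approx(51 * 2.0**-50, rel=1e-9)
    assert p49 > 1e-15


def test_sign_test_balanced():
    # sum_{k>=25} C(50,k)/2^50
    expected = sum(comb(50, k) for k in range(25, 51)) / 2**50
    assert sign_test(PairedComparison(25, 25)).p == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.556, abs=5e-3)


def test_sign_test_ties_dropped_and_all_ties_flagged():
    res = sign_test(PairedComparison(0, 0, 50))
    assert res.p == 1.0 and "all_ties" in res.flags
    # ties reduce n: 3 wins 1 loss regardless of tie count
    assert sign_test(PairedComparison(3, 1, 10)).p == sign_test(PairedComparison(3, 1)).p


def test_paired_comparison_from_pairs():
    comp = PairedComparison.from_pairs([3, 2, 1, 5], [1, 2, 4, 4])
    assert (comp.n_wins, comp.n_losses, comp.n_ties) == (2, 1, 1)


# ---------------------------------------------------------------------------
# Corrected resampled t-test


def test_corrected_t_zero_diffs_gives_p1():
    assert corrected_resampled_ttest(np.zeros(50), 1 / 3).p == 1.0


def test_corrected_t_reduces_to_classical_resampled_t_at_zero_fraction():
    rng = np.random.default_rng(5)
    d = rng.normal(0.01, 0.005, 50)
    ours = corrected_resampled_ttest(d, 0.0)
    t_classic, p_classic = sps.ttest_1samp(d, 0.0, alternative="greater")
    assert ours.statistic == pytest.approx(t_classic, rel=1e-9)
    assert ours.p == pytest.approx(p_classic, rel=1e-9)


def test_corrected_t_is_more_conservative_than_uncorrected():
    rng = np.random.default_rng(7)
    d = 0.02 + rng.normal(0, 1e-3, 50)
    corrected = corrected_resampled_ttest(d, 1 / 3)
    uncorrected = corrected_resampled_ttest(d, 0.0)
    assert corrected.p > uncorrected.p
    # variance term inflated by k * test_fraction: t shrinks by sqrt(1 + k*f)
    k = 50
    assert corrected.statistic == pytest.approx(
        uncorrected.statistic / np.sqrt(1 + k * (1 / 3)), rel=1e-9
    )


def test_corrected_t_degenerate_constant_positive():
    res = corrected_resampled_ttest(np.full(10, 0.3), 1 / 3)
    assert res.p == 0.0 and "degenerate" in res.flags


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney_oracle(x, y):
    """Two-sided p by enumerating all C(n+m, n) label assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(xs, ys):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in xs for yi in ys
        )

    obs = abs(u_stat(x, y) - len(x) * len(y) / 2)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        if abs(u - len(x) * len(y) / 2) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def test_mann_whitney_separated_samples_exact():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.p == pytest.approx(0.1, rel=1e-9)
    assert res.direction == "y"


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mann_whitney_matches_labeling_enumeration(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 5)
    y = rng.normal(0.8, 1, 5)
    res = mann_whitney(x, y)
    assert res.p == pytest.approx(mann_whitney_oracle(x, y), rel=1e-9)


def test_mann_whitney_identical_multisets_no_preference():
    res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p > 0.9 and res.direction == ""


def test_mann_whitney_shifted_normals_direction():
    rng = np.random.default_rng(3)
    x = rng.normal(2, 1, 100)
    y = rng.normal(0, 1, 100)
    res = mann_whitney(x, y)
    assert res.p < 1e-3 and res.direction == "x"


# ---------------------------------------------------------------------------
# Fisher's exact


def fisher_oracle(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration (probability-mass rule)."""
    n1, n2, m = a + b, c + d, a + c
    N = n1 + n2

    def prob(k):
        if k < max(0, m - n2) or k > min(m, n1):
            return 0.0
        return comb(n1, k) * comb(n2, m - k) / comb(N, m)

    p_obs = prob(a)
    return sum(prob(k) for k in range(0, m + 1) if prob(k) <= p_obs * (1 + 1e-9))


@pytest.mark.parametrize(
    "table", [(5, 0, 0, 5), (3, 7, 6, 4), (1, 9, 9, 1), (4, 4, 4, 4), (0, 10, 10, 0), (2, 8, 5, 15)]
)
def test_fisher_matches_hypergeometric_enumeration(table):
    res = fisher_exact(Contingency2x2(*table))
    assert res.p == pytest.approx(fisher_oracle(*table), rel=1e-9)


def test_fisher_disjoint_table():
    res = fisher_exact(Contingency2x2(5, 0, 0, 5))
    assert res.p == pytest.approx(2 / comb(10, 5), rel=1e-9)


def test_fisher_identical_proportions_ratio_one():
    res = fisher_exact(Contingency2x2(10, 30, 20, 60))
    assert res.ratio == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)


def test_fisher_enrichment_ratio_formula():
    res = fisher_exact(Contingency2x2(40, 11, 100, 900))
    assert res.ratio == pytest.approx((40 / 51) / (100 / 1000), rel=1e-12)


def test_fisher_empty_margin_flagged():
    res = fisher_exact(Contingency2x2(0, 0, 5, 5))
    assert np.isnan(res.ratio) and "empty_margin" in res.flags


# ---------------------------------------------------------------------------
# BWS permutation test


def test_bws_exhaustive_small_samples():
    """n=m=3: the permutation null is enumerated over all 20 splits, so the
    p-value is a multiple of 1/20 and reproducible without a seed."""
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    res = bws_test(x, y)
    assert res.p * 20 == pytest.approx(round(res.p * 20))
    res2 = bws_test(x, y, seed=99)
    assert res.p == res2.p  # exhaustive mode ignores the seed


def test_bws_identical_small_samples_large_p():
    res = bws_test([1.0, 2.0, 3.0], [1.5, 2.5, 0.5])
    assert res.p > 0.3


def test_bws_monte_carlo_agrees_with_exhaustive():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 4)
    y = rng.normal(1, 1, 4)
    exact = bws_test(x, y)
    mc = bws_test(x, y, n_perm=20000, seed=2, exhaustive_limit=1)
    assert mc.p == pytest.approx(exact.p, abs=0.02)


def test_bws_detects_strong_shift():
    rng = np.random.default_rng(8)
    x = rng.normal(2.0, 1, 30)
    y = rng.normal(0.0, 1, 30)
    assert bws_test(x, y, seed=1).p < 0.01


# ---------------------------------------------------------------------------
# Null calibration of the suite's tests


@pytest.mark.parametrize(
    "testfn",
    [
        lambda x, y: mann_whitney(x, y).p,
        lambda x, y: bws_test(x, y, n_perm=200, seed=0).p,
    ],
    ids=["mann_whitney", "bws"],
)
def test_type_I_error_calibrated_under_null(testfn):
    """Both samples from one distribution: rejection rate at alpha=0.05
    stays within binomial error of nominal."""
    rng = np.random.default_rng(123)
    n_rep, alpha = 400, 0.05
    rejects = sum(
        testfn(rng.normal(0, 1, 12), rng.normal(0, 1, 12)) < alpha
        for _ in range(n_rep)
    )
    se = np.sqrt(alpha * (1 - alpha) / n_rep)
    assert abs(rejects / n_rep - alpha) < 4 * se + 1 / n_rep


def test_permutation_pvalue_ratio_statistic():
    rng = np.random.default_rng(9)
    vals = np.concatenate([rng.lognormal(1.5, 0.3, 40), rng.lognormal(0, 0.3, 160)])
    labels = np.zeros(200, dtype=bool)
    labels[:40] = True
    p = permutation_pvalue(vals, labels, lambda a, b: a.mean() / b.mean(), seed=3)
    assert p < 0.01
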