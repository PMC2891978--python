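"""Statistical tests used throughout the detection pipeline.

The workhorse is the exact one-sided sign test on paired cross-validation
outcomes; a corrected resampled t-test (Nadeau & Bengio) gives the
conservative companion p-value; Mann-Whitney, Fisher's exact and the
Baumgartner-Weiss-Schindler (BWS) permutation test serve the downstream
optimal-codon, enrichment and expression analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import scipy.stats as sps


@dataclass
class TestResult:
    statistic: float
    p: float
    n: int
    method: str
    direction: str = ""
    flags: tuple = ()


# ---------------------------------------------------------------------------
# Sign test


@dataclass
class PairedComparison:
    """Win/loss/tie tally over paired observations."""

    n_wins: int
    n_losses: int
    n_ties: int = 0

    @classmethod
    def from_pairs(cls, treated, control):
        treated = np.asarray(treated, dtype=float)
        control = np.asarray(control, dtype=float)
        if treated.shape != control.shape:
            raise ValueError("paired arrays differ in length")
        wins = int(np.sum(treated > control))
        losses = int(np.sum(treated < control))
        ties = treated.size - wins - losses
        return cls(wins, losses, ties)


def sign_test(comparison: PairedComparison) -> TestResult:
    """One-sided exact sign test: are wins more frequent than chance?

    Ties are dropped (classical convention); p = P[Binom(n, 1/2) >= wins]
    with n = wins + losses. All-tie input is reported as p = 1 with a
    ``all_ties`` flag. 50 wins out of 50 gives p = 2^-50 ~ 8.9e-16, the
    only outcome of a 50-run protocol below the 1e-15 threshold.
    """
    w, l = comparison.n_wins, comparison.n_losses
    n = w + l
    if n == 0:
        return TestResult(0.0, 1.0, 0, "sign", flags=("all_ties",))
    p = float(sps.binom.sf(w - 1, n, 0.5))
    return TestResult(float(w), p, n, "sign")


# ---------------------------------------------------------------------------
# Corrected resampled t-test


def corrected_resampled_ttest(diffs, test_fraction: float) -> TestResult:
    """One-sided corrected paired t-test for repeated cross-validation.

    The naive resampled t-test is anti-conservative because the k
    measurements share training data; the correction inflates the variance
    term from var/k to (1/k + n_test/n_train) * var. For 4-fold CV the
    test fraction is (1/4)/(3/4) = 1/3. With test_fraction = 0 the
    statistic reduces exactly to the classical resampled t.
    """
    d = np.asarray(diffs, dtype=float)
    k = d.size
    if k < 2:
        raise ValueError("need at least 2 paired measurements")
    mean, var = d.mean(), d.var(ddof=1)
    if np.all(d == d[0]):
        var = 0.0
    if var == 0.0:
        if mean == 0.0:
            return TestResult(0.0, 1.0, k, "corrected_t", flags=("zero_variance",))
        p = 0.0 if mean > 0 else 1.0
        return TestResult(np.inf * np.sign(mean), p, k, "corrected_t", flags=("degenerate",))
    t = mean / np.sqrt((1.0 / k + test_fraction) * var)
    p = float(sps.t.sf(t, df=k - 1))
    return TestResult(float(t), p, k, "corrected_t")


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U with direction of the shift.

    Exact null distribution for small tie-free samples, tie-corrected
    normal approximation otherwise. ``direction`` is "x" when x tends to
    exceed y, "y" for the converse, "" for a dead tie.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    expected = x.size * y.size / 2.0
    if res.statistic > expected:
        direction = "x"
    elif res.statistic < expected:
        direction = "y"
    else:
        direction = ""
    return TestResult(
        float(res.statistic), float(res.pvalue), x.size + y.size,
        "mann_whitney", direction=direction,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test


@dataclass
class Contingency2x2:
    a: int
    b: int
    c: int
    d: int

    def as_array(self):
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class ContingencyResult:
    table: Contingency2x2
    p: float
    ratio: float
    flags: tuple = ()


def fisher_exact(table: Contingency2x2) -> ContingencyResult:
    """Two-sided Fisher's exact test plus the enrichment ratio.

    The ratio compares row proportions: (a/(a+b)) / (c/(c+d)) — e.g. the
    OCU rate inside a category over the rate outside it. An empty margin
    leaves the ratio undefined (NaN, flagged).
    """
    t = table.as_array()
    if (t < 0).any():
        raise ValueError("negative count in contingency table")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    flags = ()
    r1, r2 = table.a + table.b, table.c + table.d
    if r1 == 0 or r2 == 0 or table.c + table.d == 0 or (table.c == 0 and table.d == 0):
        ratio, flags = float("nan"), ("empty_margin",)
    else:
        p1 = table.a / r1
        p2 = table.c / r2
        if p2 == 0:
            ratio, flags = float("inf") if p1 > 0 else float("nan"), ("zero_background",)
        else:
            ratio = p1 / p2
    return ContingencyResult(table, float(p), ratio, flags)


# ---------------------------------------------------------------------------
# Baumgartner-Weiss-Schindler permutation test


def bws_test(x, y, n_perm: int = 10000, seed: int = 0, exhaustive_limit: int = 20000) -> TestResult:
    """Two-sided BWS rank test evaluated by permutation.

    When the number of distinct label assignments C(n+m, n) does not exceed
    ``exhaustive_limit`` the null distribution is enumerated exhaustively;
    otherwise ``n_perm`` Monte-Carlo permutations are drawn with ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if comb(x.size + y.size, x.size) <= exhaustive_limit:
        method = sps.PermutationMethod(n_resamples=np.inf)
    else:
        method = sps.PermutationMethod(
            n_resamples=n_perm, rng=np.random.default_rng(seed)
        )
    res = sps.bws_test(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), x.size + y.size, "bws")


# ---------------------------------------------------------------------------
# Generic one-sided permutation test for a statistic of a 2-group split


def permutation_pvalue(values, labels, statistic, n_perm: int = 2000, seed: int = 0) -> float:
    """P[statistic(permuted split) >= statistic(observed split)].

    ``labels`` is boolean; ``statistic(values_in, values_out)`` maps the two
    groups to a scalar. The observed split is included in the permutation
    set (add-one convention) so p is never 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    obs = statistic(values[labels], values[~labels])
    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if statistic(values[lab], values[~lab]) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)
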