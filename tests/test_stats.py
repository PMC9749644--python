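"""Statistical kernel tests against independent oracles.

Every non-trivial operation is checked against a from-scratch oracle:
Fisher exact against full hypergeometric enumeration, BH against the
hand-applied step-up rule, Mann-Whitney against rank-split enumeration.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from combimine.stats import (
    ContingencyTable2x2,
    bh_adjust,
    bootstrap_proportion_ci,
    fisher_exact_many,
    fisher_exact_p,
    hwe_exact_p,
    mann_whitney_u,
    odds_ratio,
    two_proportion_z,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration of all 2x2 tables at fixed
    margins, in exact rational-ish arithmetic via log factorials."""
    n1, n2, m = a + b, c + d, a + c

    def pmf(k):
        return (
            comb(n1, k, exact=True) * comb(n2, m - k, exact=True)
            / comb(n1 + n2, m, exact=True)
        )

    lo, hi = max(0, m - n2), min(m, n1)
    obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= obs * (1 + 1e-9))


def mwu_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank splits."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled))  # no ties assumed

    def u_of(idx):
        r = sum(ranks[list(idx)]) + len(idx)  # 1-based rank sum
        u1 = r - len(idx) * (len(idx) + 1) / 2
        return min(u1, n * m - u1)

    u_obs = u_of(range(n))
    total = hits = 0
    for idx in itertools.combinations(range(n + m), n):
        total += 1
        if u_of(idx) <= u_obs:
            hits += 1
    return u_obs, hits / total


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by enumerating all genotype tables at fixed allele counts."""
    n = n_aa + n_ab + n_bb
    nb = 2 * n_bb + n_ab

    def prob(het):
        from fractions import Fraction

        hom_b = (nb - het) // 2
        hom_a = n - het - hom_b
        num = (
            math.factorial(n) * 2**het * math.factorial(nb) * math.factorial(2 * n - nb)
        )
        den = (
            math.factorial(hom_a)
            * math.factorial(het)
            * math.factorial(hom_b)
            * math.factorial(2 * n)
        )
        return float(Fraction(num, den))

    minor = min(nb, 2 * n - nb)
    hets = range(minor % 2, minor + 1, 2)
    obs = prob(n_ab)
    return sum(prob(h) for h in hets if prob(h) <= obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# odds ratio
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "table, expected",
    [
        ((10, 90, 5, 95), 950 / 450),
        ((5, 5, 5, 5), 1.0),
        ((12, 8, 1, 19), (12 * 19) / (8 * 1)),
    ],
)
def test_odds_ratio_cross_product(table, expected):
    assert odds_ratio(ContingencyTable2x2(*table)) == pytest.approx(expected)


def test_odds_ratio_haldane_correction_only_on_zero_cells():
    t = ContingencyTable2x2(20, 80, 0, 100)
    assert odds_ratio(t) == pytest.approx((20.5 * 100.5) / (80.5 * 0.5))
    assert math.isinf(odds_ratio(t, correction=False))
    # no zero cell: correction leaves the table untouched
    t2 = ContingencyTable2x2(10, 90, 5, 95)
    assert odds_ratio(t2, correction=True) == odds_ratio(t2, correction=False)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def test_fisher_small_example_matches_enumeration():
    p = fisher_exact_p(ContingencyTable2x2(1, 9, 9, 1))
    assert p == pytest.approx(fisher_oracle(1, 9, 9, 1), abs=1e-12)
    assert p == pytest.approx(0.0011, abs=1e-4)


def test_fisher_label_symmetry():
    assert fisher_exact_p(ContingencyTable2x2(3, 7, 8, 2)) == pytest.approx(
        fisher_exact_p(ContingencyTable2x2(8, 2, 3, 7)), abs=1e-12
    )


def test_fisher_matches_enumeration_all_tables_up_to_n40():
    """Scalar and vectorised Fisher both agree with the full-enumeration
    oracle on every table with N <= 40."""
    rng = np.random.default_rng(0)
    checked = 0
    for n1 in range(1, 21, 3):
        for n2 in range(1, 41 - n1, 4):
            aa, cc = [], []
            for a in range(n1 + 1):
                for c in range(n2 + 1):
                    aa.append(a)
                    cc.append(c)
            aa, cc = np.array(aa), np.array(cc)
            vec = fisher_exact_many(aa, n1, cc, n2)
            for a, c, pv in zip(aa, cc, vec):
                oracle = fisher_oracle(a, n1 - a, c, n2 - c)
                assert abs(pv - oracle) < 1e-12
                checked += 1
                if rng.random() < 0.02:  # spot-check the scipy-backed scalar
                    assert fisher_exact_p(
                        ContingencyTable2x2(a, n1 - a, c, n2 - c)
                    ) == pytest.approx(oracle, abs=1e-12)
    assert checked > 2000


# ---------------------------------------------------------------------------
# two-proportion z
# ---------------------------------------------------------------------------

def test_two_proportion_z_identical_proportions():
    z, p = two_proportion_z(ContingencyTable2x2(5, 5, 5, 5))
    assert z == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_two_proportion_z_direction_and_symmetry():
    z1, p1 = two_proportion_z(ContingencyTable2x2(30, 70, 10, 90))
    z2, p2 = two_proportion_z(ContingencyTable2x2(10, 90, 30, 70))
    assert z1 > 0 > z2
    assert p1 == pytest.approx(p2)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_step_up_hand_example():
    # thresholds 0.0125 / 0.025 / 0.0375 / 0.05: the largest k with
    # p(k) <= k*alpha/m is 3
    q, reject = bh_adjust([0.01, 0.02, 0.03, 0.5], alpha=0.05)
    assert reject.sum() == 3
    assert not reject[3]


def test_bh_degenerate_lists():
    _, reject = bh_adjust([1.0, 1.0, 1.0])
    assert reject.sum() == 0
    q, reject = bh_adjust([0.04])
    assert reject.sum() == 1 and q[0] == pytest.approx(0.04)


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40),
    st.sampled_from([0.01, 0.05, 0.1]),
)
def test_bh_rejects_at_least_bonferroni(pvals, alpha):
    _, bh = bh_adjust(pvals, alpha=alpha)
    bonf = np.asarray(pvals) <= alpha / len(pvals)
    assert bh.sum() >= bonf.sum()


def test_bh_qvalues_monotone_in_sorted_p():
    q, _ = bh_adjust([0.001, 0.01, 0.02, 0.8, 0.3])
    order = np.argsort([0.001, 0.01, 0.02, 0.8, 0.3])
    assert np.all(np.diff(q[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mwu_exact_small_sample_vs_enumeration():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    u, p = mann_whitney_u(x, y)
    u_oracle, p_oracle = mwu_oracle(np.array(x), np.array(y))
    assert u == pytest.approx(u_oracle) == 0.0
    assert p == pytest.approx(p_oracle) == pytest.approx(0.1)


def test_mwu_symmetry_and_identity():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=12), rng.normal(1.0, size=9)
    _, p_xy = mann_whitney_u(x, y)
    _, p_yx = mann_whitney_u(y, x)
    assert p_xy == pytest.approx(p_yx)
    _, p_same = mann_whitney_u(x, x)
    assert p_same == pytest.approx(1.0)


def test_mwu_all_tied_warns_p_one():
    with pytest.warns(UserWarning):
        _, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
    assert p == 1.0


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------

def test_bootstrap_degenerate_and_plugin_point():
    assert bootstrap_proportion_ci([1, 1, 1, 1], seed=0) == (1.0, 1.0, 1.0)
    flags = [1, 0, 0, 1, 0, 1, 1, 0, 0, 0]
    point, lo, hi = bootstrap_proportion_ci(flags, seed=3)
    assert point == pytest.approx(0.4)
    assert lo <= point <= hi


def test_bootstrap_deterministic_and_reasonable_coverage():
    rng = np.random.default_rng(42)
    covered = 0
    n_rep = 60
    for i in range(n_rep):
        flags = rng.random(400) < 0.3
        _, lo, hi = bootstrap_proportion_ci(flags, n_boot=400, seed=i)
        covered += lo <= 0.3 <= hi
    # nominal 95%: allow generous binomial slack at 60 replicates
    assert covered >= 0.85 * n_rep
    a = bootstrap_proportion_ci([0, 1, 1, 0, 1], n_boot=200, seed=9)
    b = bootstrap_proportion_ci([0, 1, 1, 0, 1], n_boot=200, seed=9)
    assert a == b


# ---------------------------------------------------------------------------
# exact HWE test
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts",
    [(50, 0, 50), (25, 50, 25), (80, 15, 5), (3, 7, 2), (0, 10, 0)],
)
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_p(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-10)


def test_hwe_extreme_het_deficit_is_tiny():
    # AA=50, Aa=0, aa=50: maximal departure, p below any usual threshold
    assert hwe_exact_p(50, 0, 50) < 1e-25
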