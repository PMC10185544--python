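"""Exact and rank statistics: hand-checked examples, brute-force oracles and
cross-checks against scipy's independent implementations."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cordssep.stats import (
    AssociationResult,
    ContingencyTable2x2,
    benjamini_hochberg,
    correlation_band,
    fisher_exact_2x2,
    grade_association_summary,
    kendall_tau_b,
    kruskal_wallis_h,
    mann_whitney_u,
)


# --------------------------------------------------------------------------
# Fisher's exact test
# --------------------------------------------------------------------------

def _fisher_bruteforce(a, b, c, d):
    """Independent enumeration oracle: rational hypergeometric mass rule."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if min(r1, c + d, c1, b + d) == 0:
        return 1.0
    k_lo, k_hi = max(0, c1 - (n - r1)), min(r1, c1)
    denom = math.comb(n, c1)
    masses = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
        for k in range(k_lo, k_hi + 1)
    }
    cutoff = masses[a] * (1 + Fraction(1, 10**7))
    return float(sum(m for m in masses.values() if m <= cutoff))


@pytest.mark.parametrize(
    "table, expected, places",
    [
        ((27, 4, 0, 4), 0.001, 3),   # grade-1 amplitude x power table
        ((24, 25, 0, 8), 0.016, 3),  # grade-2
        ((15, 12, 0, 7), 0.011, 3),  # grade-3
        ((1, 1, 1, 1), 1.0, 12),     # perfectly balanced
    ],
)
def test_fisher_known_tables(table, expected, places):
    res = fisher_exact_2x2(ContingencyTable2x2(*table))
    assert round(res.p_value, places) == expected


def test_fisher_exact_rational_case():
    # margins (2,2)/(2,2): three tables with masses 1/6, 4/6, 1/6
    res = fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2))
    assert res.p_value == pytest.approx(1 / 3, abs=1e-15)


def test_fisher_zero_margin_degenerate():
    res = fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 5))
    assert res.p_value == 1.0


def test_fisher_matches_bruteforce_and_scipy(rng):
    for _ in range(300):
        n = int(rng.integers(1, 61))
        cells = rng.multinomial(n, [0.25] * 4)
        table = ContingencyTable2x2(*map(int, cells))
        p = fisher_exact_2x2(table).p_value
        assert p == pytest.approx(_fisher_bruteforce(*map(int, cells)), abs=1e-12)
        assert p == pytest.approx(sps.fisher_exact(table.as_array())[1], abs=1e-9)


# --------------------------------------------------------------------------
# Kendall tau-b
# --------------------------------------------------------------------------

def _tau_b_allpairs(x, y):
    """Plain double-loop oracle with tie bookkeeping."""
    n = len(x)
    conc = disc = tie_x = tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tie_x += 1
                tie_y += 1
            elif dx == 0:
                tie_x += 1
            elif dy == 0:
                tie_y += 1
            elif (dx > 0) == (dy > 0):
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    return (conc - disc) / math.sqrt((n0 - tie_x) * (n0 - tie_y))


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 2, 3), (1, 2, 3), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 1, 2, 3), (1, 2, 2, 3), 0.8),  # C=4, D=0, one tie each side
    ],
)
def test_tau_known_values(x, y, expected):
    assert kendall_tau_b(x, y).statistic == pytest.approx(expected, abs=1e-12)


def test_tau_matches_allpairs_oracle_and_scipy(rng):
    for _ in range(40):
        n = int(rng.integers(3, 120))
        x = rng.integers(0, max(2, n // 3), size=n).astype(float)  # many ties
        y = x * rng.choice([-1, 1]) + rng.normal(0, 2, size=n).round(1)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        res = kendall_tau_b(x, y)
        assert res.statistic == pytest.approx(_tau_b_allpairs(x, y), abs=1e-12)
        sp = sps.kendalltau(x, y)
        assert res.statistic == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(sp.pvalue, abs=1e-8)


def test_tau_exact_permutation_small_n():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
    p_perm = kendall_tau_b(x, y, method="permutation").p_value
    p_scipy = sps.kendalltau(x, y, method="exact").pvalue
    assert p_perm == pytest.approx(p_scipy, abs=1e-12)


def test_tau_all_tied_is_error():
    with pytest.raises(ValueError):
        kendall_tau_b([1, 1, 1], [1, 2, 3])


# --------------------------------------------------------------------------
# Kruskal-Wallis and Mann-Whitney
# --------------------------------------------------------------------------

def test_kruskal_known_values():
    assert kruskal_wallis_h([(1, 2, 3), (4, 5, 6), (7, 8, 9)]).statistic == pytest.approx(7.2)
    assert kruskal_wallis_h([(1, 2), (3, 4)]).statistic == pytest.approx(2.4)


def test_kruskal_identical_groups_no_separation():
    res = kruskal_wallis_h([(1.0, 2.0, 5.0), (1.0, 2.0, 5.0)])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_kruskal_matches_scipy(rng):
    for _ in range(25):
        groups = [rng.integers(0, 8, size=int(rng.integers(2, 15))).astype(float) for _ in range(3)]
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            continue
        res = kruskal_wallis_h(groups)
        sp = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(sp.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(sp.pvalue, abs=1e-10)


def test_kruskal_all_identical_is_error():
    with pytest.raises(ValueError):
        kruskal_wallis_h([(3.0, 3.0), (3.0, 3.0)])


@pytest.mark.parametrize(
    "x, y, expected_u",
    [
        ((1, 2), (3, 4), 0.0),        # complete separation
        ((1, 3), (2, 4), 1.0),        # one crossing pair
        ((1, 2, 3), (1, 2, 3), 4.5),  # identical multisets: U = n^2/2
    ],
)
def test_mann_whitney_known_u(x, y, expected_u):
    assert mann_whitney_u(x, y).statistic == pytest.approx(expected_u)


def test_mann_whitney_matches_scipy(rng):
    for _ in range(25):
        nx, ny = int(rng.integers(3, 20)), int(rng.integers(3, 20))
        x = rng.normal(0, 1, nx).round(1)
        y = rng.normal(0.4, 1, ny).round(1)
        res = mann_whitney_u(x, y, method="asymptotic")
        sp = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u_sp = min(sp.statistic, nx * ny - sp.statistic)
        assert res.statistic == pytest.approx(u_sp)
        assert res.p_value == pytest.approx(sp.pvalue, abs=1e-9)


def test_mann_whitney_exact_matches_scipy_without_ties():
    x = [0.3, 1.7, 2.2, 4.5]
    y = [0.9, 2.8, 3.1, 3.3, 5.0]
    res = mann_whitney_u(x, y, method="exact")
    sp = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert res.p_value == pytest.approx(sp.pvalue, abs=1e-12)


# --------------------------------------------------------------------------
# shared properties
# --------------------------------------------------------------------------

@given(
    st.lists(st.integers(min_value=-20, max_value=20), min_size=4, max_size=30),
    st.integers(min_value=1, max_value=5),
)
def test_rank_statistics_invariant_under_monotone_transform(values, scale):
    """tau, U and H depend on ranks only, so any strictly increasing map of
    the data leaves them unchanged."""
    x = np.asarray(values, dtype=float)
    y = np.arange(len(x), dtype=float)

    def f(v):
        return np.exp(v / 40.0) * scale + 3.0  # strictly increasing

    if not np.all(x == x[0]):
        assert kendall_tau_b(x, y).statistic == pytest.approx(
            kendall_tau_b(f(x), y).statistic, abs=1e-12
        )
    half = len(x) // 2
    a, b = x[:half], x[half:]
    assert mann_whitney_u(a, b).statistic == pytest.approx(
        mann_whitney_u(f(a), f(b)).statistic
    )
    if not np.all(x == x[0]):
        assert kruskal_wallis_h([a, b]).statistic == pytest.approx(
            kruskal_wallis_h([f(a), f(b)]).statistic, abs=1e-10
        )


def test_p_value_range_enforced():
    with pytest.raises(ValueError):
        AssociationResult("bad", 0.0, 1.5, 3)


def test_correlation_bands():
    assert correlation_band(0.1) == "low"
    assert correlation_band(-0.45) == "moderate"
    assert correlation_band(0.9) == "high"


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    p = [0.001, 0.02, 0.03, 0.5, 0.04, 0.8]
    adj = benjamini_hochberg(p)
    _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(adj, adj_sm)


def test_grade_association_summary_structure(rng):
    import pandas as pd

    n = 60
    grade = rng.integers(0, 4, n)
    df = pd.DataFrame(
        {
            "grade": grade,
            "mscc": grade * 10 + rng.normal(0, 2, n),
            "amp": 2.5 - grade * 0.4 + rng.normal(0, 0.2, n),
        }
    )
    tables = {1: ContingencyTable2x2(27, 4, 0, 4)}
    out = grade_association_summary(df, grade_tables=tables)
    k = len(out["variables"])
    tau = np.asarray(out["kendall_tau_b"]["tau"])
    assert tau.shape == (k, k)
    assert np.allclose(tau, tau.T)
    assert tau[0, 1] < 0  # mscc up, amplitude down
    assert out["fisher_by_grade"][1]["p_value"] == pytest.approx(0.001337, abs=5e-7)
    assert all(v["p_value"] is None or 0 <= v["p_value"] <= 1 for v in out["kruskal_wallis"].values())
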