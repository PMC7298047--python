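"""2x2 statistics: chi-squared (Yates), Fisher exact, BH step-up."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from repurpose.enrichment_stats import (ContingencyTable, bh_fdr, chi_squared,
                                        fisher_exact)


def fisher_brute(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by enumerating all tables with the margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)
    pmf = {
        x: Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)
        for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    }
    observed = pmf[a]
    return sum(p for p in pmf.values() if p <= observed)


def bh_brute(p_values):
    """Step-up BH by direct definition: q(i) = min_{j>=i} p(j)*m/j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = running
    return q


class TestChiSquared:
    def test_zero_event_cohort_vs_background(self):
        res = chi_squared(ContingencyTable(0, 1000, 10, 990), continuity_correction=True)
        assert res.statistic == pytest.approx(8.1407, abs=1e-3)
        assert res.p_value == pytest.approx(4.33e-3, rel=1e-2)

    def test_single_event_large_cohort(self):
        res = chi_squared(ContingencyTable(1, 1487, 10, 990), continuity_correction=True)
        assert res.p_value == pytest.approx(1.747e-3, rel=1e-2)

    def test_yates_clamp_at_equal_odds(self):
        res = chi_squared(ContingencyTable(5, 995, 5, 995), continuity_correction=True)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="degenerate margin"):
            chi_squared(ContingencyTable(0, 0, 5, 5))

    def test_real_valued_cells_accepted(self):
        res = chi_squared(ContingencyTable(3.546, 996.454, 10, 990))
        assert 0 < res.p_value <= 1

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_uncorrected_equals_observed_expected_form(self, cells):
        """Shortcut n(ad-bc)^2/(margins) equals sum (O-E)^2/E."""
        a, b, c, d = cells
        table = ContingencyTable(a, b, c, d)
        res = chi_squared(table, continuity_correction=False)
        n = a + b + c + d
        r = (a + b, c + d)
        col = (a + c, b + d)
        expected = [[ri * cj / n for cj in col] for ri in r]
        obs = [[a, b], [c, d]]
        stat = sum(
            (obs[i][j] - expected[i][j]) ** 2 / expected[i][j]
            for i in range(2) for j in range(2)
        )
        assert res.statistic == pytest.approx(stat, rel=1e-10)

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(1, 50)] * 4), st.booleans())
    def test_row_and_column_swap_invariance(self, cells, correction):
        a, b, c, d = cells
        base = chi_squared(ContingencyTable(a, b, c, d), correction)
        swapped = chi_squared(ContingencyTable(d, c, b, a), correction)
        assert swapped.statistic == pytest.approx(base.statistic, rel=1e-12)
        assert swapped.p_value == pytest.approx(base.p_value, rel=1e-12)


class TestFisherExact:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((1, 1, 1, 1), 1.0),
            ((0, 2, 2, 0), 1.0 / 3.0),
            ((0, 0, 0, 1), 1.0),
        ],
    )
    def test_small_table_examples(self, cells, expected):
        assert fisher_exact(ContingencyTable(*cells)).p_value == pytest.approx(expected)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fisher_exact(ContingencyTable(0.5, 1, 1, 1))

    @settings(derandomize=True, max_examples=150)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_matches_enumeration_and_scipy(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p = fisher_exact(ContingencyTable(a, b, c, d)).p_value
        assert p == pytest.approx(float(fisher_brute(a, b, c, d)), rel=1e-9)
        p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert p == pytest.approx(p_scipy, rel=1e-7)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.3], [0.3]),
            ([0.005, 0.5], [0.01, 0.5]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_brute_force_and_invariants(self, p):
        q = bh_fdr(p)
        assert q == pytest.approx(bh_brute(p), rel=1e-12, abs=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        # permutation equivariance
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        q_perm = bh_fdr([p[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm], rel=1e-12, abs=1e-12)
        # monotone along sorted p
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-15)
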