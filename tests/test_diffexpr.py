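"""Exact two-library tests, BH adjustment and call logic."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from triploidexpr.diffexpr import (DEThresholds, bh_fdr, binomial_rs_test,
                                   compare_groups, de_call, fisher_de_test)

from conftest import make_matrix


def binomial_enumeration(c1, t, prob):
    """Independent oracle: sum of binomial point probabilities <= P(observed)."""
    pmf = [math.comb(t, k) * prob**k * (1 - prob) ** (t - k) for k in range(t + 1)]
    p_obs = pmf[c1]
    return min(1.0, sum(p for p in pmf if p <= p_obs * (1 + 1e-7)))


def fisher_enumeration(c1, c2, n1, n2):
    """Independent oracle: hypergeometric point-probability enumeration."""
    t, n_total = c1 + c2, n1 + n2
    lo, hi = max(0, t - n2), min(t, n1)
    pmf = {k: math.comb(n1, k) * math.comb(n2, t - k) / math.comb(n_total, t)
           for k in range(lo, hi + 1)}
    p_obs = pmf[c1]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def bh_step_up(p_values):
    """Independent oracle: literal Benjamini-Hochberg step-up."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = running
    return q


class TestBinomialRandomSampling:
    @pytest.mark.parametrize("c1, c2, expected", [
        (5, 5, 1.0),                 # observation at the mode
        (0, 10, 2 / 1024),           # symmetric extremes
        (4, 0, 2 / 16),
    ])
    def test_equal_depth_examples(self, c1, c2, expected):
        assert binomial_rs_test(c1, c2, 10**6, 10**6) == pytest.approx(expected)

    def test_zero_total_is_uninformative(self):
        assert binomial_rs_test(0, 0, 10, 10) == 1.0

    @pytest.mark.parametrize("n1, n2", [(10**6, 10**6), (3 * 10**6, 10**6)])
    def test_matches_enumeration_small_totals(self, n1, n2):
        prob = n1 / (n1 + n2)
        for t in range(1, 21):
            for c1 in range(t + 1):
                assert binomial_rs_test(c1, t - c1, n1, n2) == pytest.approx(
                    binomial_enumeration(c1, t, prob), rel=1e-9)


class TestFisher:
    def test_disjoint_table(self):
        assert fisher_de_test(0, 5, 5, 5) == pytest.approx(2 / 252)

    def test_identical_rows_are_null(self):
        assert fisher_de_test(3, 3, 9, 9) == 1.0

    @given(c1=st.integers(0, 20), c2=st.integers(0, 20),
           e1=st.integers(0, 15), e2=st.integers(0, 15))
    def test_symmetry_under_group_swap(self, c1, c2, e1, e2):
        n1, n2 = c1 + e1 + 1, c2 + e2 + 1
        assert fisher_de_test(c1, c2, n1, n2) == pytest.approx(
            fisher_de_test(c2, c1, n2, n1), rel=1e-9)

    def test_count_above_library_rejected(self):
        with pytest.raises(ValueError):
            fisher_de_test(6, 0, 5, 5)

    def test_matches_hypergeometric_enumeration(self):
        for n1, n2 in [(5, 5), (12, 18), (25, 25)]:
            for c1 in range(n1 + 1):
                for c2 in range(n2 + 1):
                    if c1 + c2 == 0:
                        continue
                    assert fisher_de_test(c1, c2, n1, n2) == pytest.approx(
                        fisher_enumeration(c1, c2, n1, n2), rel=1e-8)


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.001, 0.01, 0.03, 0.8]),
                                   [0.004, 0.02, 0.04, 0.8])

    def test_single_and_constant_inputs_are_fixed_points(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_step_up_oracle(self, p_values):
        np.testing.assert_allclose(bh_fdr(p_values), bh_step_up(p_values),
                                   atol=1e-12)

    @given(st.permutations(list(range(8))))
    def test_permutation_equivariance(self, perm):
        base = [0.001, 0.02, 0.02, 0.15, 0.3, 0.55, 0.8, 1.0]
        permuted = [base[i] for i in perm]
        q_base = bh_fdr(base)
        q_perm = bh_fdr(permuted)
        np.testing.assert_allclose(q_perm, [q_base[i] for i in perm])


class TestDeCall:
    @pytest.mark.parametrize("m, q, expected", [
        (2.3, 1e-5, "up"),
        (2.3, 0.01, "ns"),       # FDR gate
        (1.0, 1e-5, "ns"),       # strict > on the fold-change boundary
        (-3.0, 1e-4, "down"),
        (float("inf"), 1e-5, "up"),
        (float("nan"), 1e-5, "ns"),
    ])
    def test_threshold_rules(self, m, q, expected):
        assert de_call(m, q, DEThresholds()) == expected


class TestCompareGroups:
    def test_identical_groups_all_ns(self):
        counts = np.tile(np.array([[40], [7], [123]]), (1, 9))
        results = compare_groups(make_matrix(counts), "paternal", "maternal")
        assert all(r.call == "ns" for r in results)
        assert all(r.p_value == 1.0 for r in results)

    def test_planted_fold_change_called_up(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(100, size=(50, 9))
        counts[0, 0:3] = 8 * 100  # 8-fold in paternal replicates
        matrix = make_matrix(counts)
        results = compare_groups(matrix, "paternal", "maternal")
        assert results[0].call == "up"
        assert results[0].m_value > 1
        # sanity: planted p verified against the enumeration model direction
        assert results[0].p_value < 0.001

    def test_direction_antisymmetry(self, small_matrix):
        fwd = compare_groups(small_matrix, "paternal", "hybrid")
        rev = compare_groups(small_matrix, "hybrid", "paternal")
        for f, r in zip(fwd, rev):
            assert f.m_value == pytest.approx(-r.m_value, nan_ok=True)
            assert f.p_value == pytest.approx(r.p_value, rel=1e-9)
            assert r.call == {"up": "down", "down": "up", "ns": "ns"}[f.call]

    def test_zero_both_sides_flagged_untested(self):
        counts = np.ones((3, 9), dtype=int) * 30
        counts[2, :6] = 0  # zero in both parental groups
        results = compare_groups(make_matrix(counts), "paternal", "maternal")
        assert results[2].tested is False
        assert results[2].call == "ns"

    def test_unknown_engine_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="unknown engine"):
            compare_groups(small_matrix, "paternal", "maternal", engine="deseq")

    def test_fisher_and_binomial_engines_agree_at_depth(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(50, size=(20, 9))
        matrix = make_matrix(counts)
        p_binom = [r.p_value for r in
                   compare_groups(matrix, "paternal", "maternal", engine="binomial")]
        p_fisher = [r.p_value for r in
                    compare_groups(matrix, "paternal", "maternal", engine="fisher")]
        np.testing.assert_allclose(p_binom, p_fisher, atol=0.02)
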