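"""Pooled-prevalence MLE, support intervals and the exact Fisher test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import gammaln

from flyvir.prevalence import (donor_group_transmission_table,
                               estimate_prevalence, estimate_transmission,
                               fisher_exact_rxc, pooled_loglik)


def grid_mle(pools, res=1e-5):
    """Brute-force grid maximizer of the pooled log-likelihood."""
    sizes = np.array([n for n, _ in pools], float)
    pos = np.array([b for _, b in pools], bool)
    p = np.arange(res, 1.0, res)
    logq = np.log1p(-p)[:, None]
    ll = (np.log1p(-np.exp(sizes[None, pos] * logq)).sum(axis=1)
          + (sizes[None, ~pos] * logq).sum(axis=1))
    return float(p[np.argmax(ll)])


class TestPooledLoglik:
    def test_impossible_data_is_minus_inf(self):
        assert pooled_loglik(0.0, [(5, True), (3, False)]) == -math.inf
        assert pooled_loglik(1.0, [(5, True), (3, False)]) == -math.inf

    def test_certain_data_is_zero(self):
        assert pooled_loglik(1.0, [(5, True), (2, True)]) == 0.0
        assert pooled_loglik(0.0, [(5, False), (2, False)]) == 0.0

    def test_single_positive_pool_arithmetic(self):
        assert pooled_loglik(0.1, [(10, True)]) == pytest.approx(
            math.log(1 - 0.9**10), abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            pooled_loglik(1.5, [(5, True)])
        with pytest.raises(ValueError):
            pooled_loglik(0.5, [])


class TestEstimatePrevalence:
    def test_all_negative_boundary(self):
        est = estimate_prevalence([(10, False)] * 5)
        assert est.p_hat == 0.0 and est.lower == 0.0
        # upper solves 50*log(1-p) = -2
        assert est.upper == pytest.approx(1 - math.exp(-2 / 50), abs=1e-9)

    def test_all_positive_boundary(self):
        est = estimate_prevalence([(10, True)] * 5)
        assert est.p_hat == 1.0 and est.upper == 1.0 and est.lower < 1.0

    @pytest.mark.parametrize("k,n", [(1, 4), (3, 7), (10, 20), (5, 30)])
    def test_unit_pools_reduce_to_binomial(self, k, n):
        pools = [(1, True)] * k + [(1, False)] * (n - k)
        assert estimate_prevalence(pools).p_hat == pytest.approx(k / n, abs=1e-6)

    def test_matches_grid_oracle_on_spec_layout(self):
        pools = [(10, True)] + [(10, False)] * 9
        est = estimate_prevalence(pools)
        assert est.p_hat == pytest.approx(grid_mle(pools), abs=2e-5)

    def test_interval_contains_mle_and_shrinks_with_replication(self):
        base = [(12, True), (8, False), (15, True), (10, False), (9, False)]
        widths = []
        for rep in (1, 4, 16):
            est = estimate_prevalence(base * rep)
            assert est.lower <= est.p_hat <= est.upper
            widths.append(est.upper - est.lower)
        assert widths[0] > widths[1] > widths[2]

    @given(st.lists(st.tuples(st.integers(1, 20), st.booleans()),
                    min_size=1, max_size=12),
           st.integers(0, 11))
    def test_flipping_negative_to_positive_raises_mle(self, pools, idx):
        idx = idx % len(pools)
        if pools[idx][1]:
            return
        flipped = list(pools)
        flipped[idx] = (pools[idx][0], True)
        assert (estimate_prevalence(flipped).p_hat
                >= estimate_prevalence(pools).p_hat - 1e-7)

    def test_empty_pool_list_rejected(self):
        with pytest.raises(ValueError):
            estimate_prevalence([])


class TestEstimateTransmission:
    def test_study_headline_rate(self):
        est = estimate_transmission(213, 606)
        assert est.rate == pytest.approx(0.3515, abs=5e-4)
        assert est.lower < est.rate < est.upper

    def test_zero_boundary(self):
        est = estimate_transmission(0, 50)
        assert est.rate == 0.0 and est.lower == 0.0 and est.upper > 0.0

    def test_bounds_match_grid_search(self):
        est = estimate_transmission(5, 20)
        pools = [(1, True)] * 5 + [(1, False)] * 15
        p = np.arange(1e-5, 1.0, 1e-5)
        ll = 5 * np.log(p) + 15 * np.log1p(-p)
        inside = p[ll >= ll.max() - 2.0]
        assert est.lower == pytest.approx(inside.min(), abs=2e-5)
        assert est.upper == pytest.approx(inside.max(), abs=2e-5)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            estimate_transmission(5, 0)
        with pytest.raises(ValueError):
            estimate_transmission(6, 5)


def enumeration_oracle(table):
    """Independent Fisher-Freeman-Halton via itertools product enumeration."""
    table = np.asarray(table, int)
    row = table.sum(axis=1)
    c1 = table[:, 0].sum()
    n = row.sum()

    def logp(col):
        lp = -(gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        for r, a in zip(row, col):
            lp += gammaln(r + 1) - gammaln(a + 1) - gammaln(r - a + 1)
        return lp

    lp_obs = logp(table[:, 0])
    total = 0.0
    for col in itertools.product(*(range(r + 1) for r in row)):
        if sum(col) == c1:
            lp = logp(col)
            if lp <= lp_obs + 1e-12:
                total += math.exp(lp)
    return min(total, 1.0)


class TestFisherExact:
    def test_donor_group_table_from_study(self):
        p = fisher_exact_rxc([[3, 1], [4, 3], [4, 12]])
        assert p == pytest.approx(0.116, abs=5e-4)

    def test_identical_proportions(self):
        assert fisher_exact_rxc([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_two_by_two_brute_force(self):
        # margins (3,3)/(3,3): four tables, observed and its mirror each 1/20
        assert fisher_exact_rxc([[3, 0], [0, 3]]) == pytest.approx(0.1, abs=1e-9)

    def test_agrees_with_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 200:
            t = rng.integers(0, 5, size=(3, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact_rxc(t) == pytest.approx(
                enumeration_oracle(t), abs=1e-9)
            checked += 1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1.5, 1], [1, 1]])
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, 0], [2, 0]])
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, 2, 3], [1, 2, 3]])


def test_donor_group_table_builder():
    t = donor_group_transmission_table({"Dmel": (4, 7), "Dimm": (3, 4),
                                        "DobsGroup": (4, 16)})
    assert t.tolist() == [[3, 1], [4, 3], [4, 12]]
    with pytest.raises(ValueError):
        donor_group_transmission_table({"Dmel": (5, 4)})
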