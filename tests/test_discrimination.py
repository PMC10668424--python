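"""PDI, conditional-risk pairwise c-statistics, binary c-statistic.

The exhaustive tuple enumeration serves as the oracle for the rank-counting
estimator, and O(n^2) pair counting as the oracle for the AUROC convention
(ties credited 1/2).
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovarisk.discrimination import (binary_cstat_any_malignancy, conditional_risk,
                                    pairwise_cstat, pairwise_cstat_matrix, pdi)


def brute_force_auc(scores, labels):
    """Mann-Whitney AUROC by O(n^2) pair counting; ties count 1/2."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_instance(rng, max_per_class=4, n_classes=5):
    sizes = rng.integers(1, max_per_class + 1, size=n_classes)
    y = np.repeat(np.arange(n_classes), sizes)
    P = rng.dirichlet(np.ones(n_classes), size=y.size)
    return P, y


class TestPdi:
    def test_uniform_probabilities_give_one_fifth(self, balanced_outcomes):
        P = np.full((balanced_outcomes.size, 5), 0.2)
        for est in ("exhaustive", "sorted_exact"):
            res = pdi(P, balanced_outcomes, estimator=est)
            assert res.overall_pdi == pytest.approx(0.2, abs=1e-12)
            assert np.allclose(res.category_pdi, 0.2, atol=1e-12)

    def test_indicator_probabilities_give_one(self, balanced_outcomes):
        P = np.eye(5)[balanced_outcomes]
        for est in ("exhaustive", "sorted_exact"):
            assert pdi(P, balanced_outcomes, estimator=est).overall_pdi == 1.0

    def test_sorted_exact_matches_exhaustive(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            P, y = random_instance(rng)
            a = pdi(P, y, estimator="exhaustive")
            b = pdi(P, y, estimator="sorted_exact")
            assert abs(a.overall_pdi - b.overall_pdi) < 1e-12
            assert np.abs(a.category_pdi - b.category_pdi).max() < 1e-12

    def test_sorted_exact_matches_exhaustive_with_ties(self):
        # coarse probabilities force many exact ties
        rng = np.random.default_rng(7)
        for _ in range(25):
            sizes = rng.integers(1, 4, size=5)
            y = np.repeat(np.arange(5), sizes)
            P = rng.integers(0, 3, size=(y.size, 5)).astype(float) + 0.5
            P /= P.sum(axis=1, keepdims=True)
            a = pdi(P, y, estimator="exhaustive")
            b = pdi(P, y, estimator="sorted_exact")
            assert abs(a.overall_pdi - b.overall_pdi) < 1e-12

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(5)
        P, y = random_instance(rng, max_per_class=8)
        exact = pdi(P, y, estimator="sorted_exact").overall_pdi
        mc = pdi(P, y, estimator="monte_carlo", seed=11, n_samples=100_000)
        assert abs(mc.overall_pdi - exact) < 3 * mc.mc_se

    def test_overall_is_mean_of_categories(self):
        rng = np.random.default_rng(9)
        P, y = random_instance(rng)
        res = pdi(P, y, estimator="sorted_exact")
        assert res.overall_pdi == pytest.approx(res.category_pdi.mean(), abs=1e-10)

    def test_absent_class_named_in_error(self):
        P = np.full((8, 5), 0.2)
        y = np.array([0, 0, 1, 1, 2, 2, 3, 3])  # sec_met absent
        with pytest.raises(ValueError, match="sec_met"):
            pdi(P, y)

    def test_label_permutation_null_near_one_fifth(self):
        rng = np.random.default_rng(31)
        P = rng.dirichlet(np.ones(5), size=100)
        y = np.repeat(np.arange(5), 20)
        vals = []
        for _ in range(30):
            vals.append(pdi(P, rng.permutation(y), estimator="sorted_exact").overall_pdi)
        assert abs(np.mean(vals) - 0.2) < 0.01


class TestConditionalRisk:
    def test_closed_form_values(self):
        P = np.array([[0.5, 0.5, 0, 0, 0],
                      [0.1, 0.3, 0.2, 0.2, 0.2],
                      [0.0, 0.0, 0.5, 0.5, 0.0]])
        cr = conditional_risk(P, 0, 1)
        assert cr[0] == pytest.approx(0.5)
        assert cr[1] == pytest.approx(0.3 / 0.4)
        assert cr[2] == pytest.approx(0.5)  # degenerate 0/0 convention

    def test_same_class_rejected(self):
        with pytest.raises(ValueError):
            conditional_risk(np.full((3, 5), 0.2), 2, 2)


class TestPairwiseCstat:
    def test_perfect_separation_gives_one(self):
        P = np.zeros((6, 5))
        P[:3, 0] = 0.9; P[:3, 1] = 0.1
        P[3:, 0] = 0.1; P[3:, 1] = 0.9
        y = np.array([0, 0, 0, 1, 1, 1])
        assert pairwise_cstat(P, y, 0, 1) == 1.0

    def test_constant_risk_gives_half(self):
        P = np.full((10, 5), 0.2)
        y = np.array([0] * 5 + [1] * 5)
        assert pairwise_cstat(P, y, 0, 1) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 5, size=n)
            while len(np.unique(y)) < 5:
                y = rng.integers(0, 5, size=n)
            P = np.round(rng.dirichlet(np.ones(5), size=n), 2)  # rounding makes ties
            P /= P.sum(axis=1, keepdims=True)
            k, l = 0, 3
            mask = (y == k) | (y == l)
            cr = conditional_risk(P[mask], k, l)
            expected = brute_force_auc(cr, (y[mask] == l))
            assert pairwise_cstat(P, y, k, l) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        P = rng.dirichlet(np.ones(5), size=n)
        base = pairwise_cstat(P, y, 0, 1)
        # exponentiating the conditional risk is strictly increasing
        cr = conditional_risk(P, 0, 1)
        assert brute_force_auc(np.exp(3 * cr), y == 1) == pytest.approx(base, abs=1e-12)

    def test_two_class_matrix_equals_binary_auroc(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(13)
        p1 = rng.random(60)
        P = np.column_stack([1 - p1, p1])
        y = rng.integers(0, 2, size=60)
        got = pairwise_cstat(P, y, 0, 1)
        assert got == pytest.approx(roc_auc_score(y == 1, p1), abs=1e-12)

    def test_empty_class_rejected(self):
        P = np.full((4, 5), 0.2)
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError):
            pairwise_cstat(P, y, 0, 4)

    def test_matrix_upper_triangle(self, balanced_outcomes):
        rng = np.random.default_rng(3)
        P = rng.dirichlet(np.ones(5), size=balanced_outcomes.size)
        M = pairwise_cstat_matrix(P, balanced_outcomes)
        assert np.isnan(np.diag(M)).all()
        iu = np.triu_indices(5, 1)
        assert np.isfinite(M[iu]).all()


class TestBinaryCstat:
    def test_perfect_and_constant(self):
        y = np.array([0, 0, 0, 2, 3, 4])
        P = np.zeros((6, 5))
        P[:3, 0] = 1.0
        P[3:, 0] = 0.0; P[3:, 2] = 1.0
        assert binary_cstat_any_malignancy(P, y) == 1.0
        assert binary_cstat_any_malignancy(np.full((6, 5), 0.2), y) == 0.5

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 5, size=8)
        y[:2] = 0; y[2] = 1
        P = rng.dirichlet(np.ones(5), size=8)
        expected = brute_force_auc(1 - P[:, 0], y != 0)
        assert binary_cstat_any_malignancy(P, y) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            binary_cstat_any_malignancy(np.full((3, 5), 0.2), np.zeros(3, int))
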