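import numpy as np
import pytest

from ovarisk.calibration import (CalibrationCurve, average_center_curves,
                                 fit_flexible_curve, multiclass_eci,
                                 pooled_calibration_curves, rescaled_eci)
from ovarisk.cohort import OUTCOME_LEVELS


def constant_curve(value, category="benign", n=100):
    grid = np.linspace(0.0, 1.0, 11)
    return CalibrationCurve(category, grid, np.full(11, float(value)), n=n)


class TestFlexibleCurve:
    def test_constant_events_give_constant_curve(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        curve = fit_flexible_curve(p, np.ones(200))
        assert np.allclose(curve.observed, 1.0)

    def test_consistency_under_perfect_calibration(self):
        rng = np.random.default_rng(1)
        p = rng.beta(2, 3, 50_000)
        y = (rng.random(50_000) < p).astype(float)
        curve = fit_flexible_curve(p, y)
        assert np.max(np.abs(curve.observed - curve.grid)) <= 0.03

    def test_independent_events_give_horizontal_curve(self):
        rng = np.random.default_rng(2)
        p = rng.random(30_000)
        y = (rng.random(30_000) < 0.3).astype(float)
        curve = fit_flexible_curve(p, y)
        assert np.max(np.abs(curve.observed - 0.3)) < 0.03

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fit_flexible_curve(np.linspace(0, 1, 10), np.zeros(10))

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_flexible_curve(np.full(50, 0.4), np.random.default_rng(3).integers(0, 2, 50))

    def test_logit_shift_pushes_curve_off_diagonal(self):
        # events drawn from logit-shifted probabilities: smoothed observed
        # rates should exceed predictions across the grid
        from scipy.special import expit, logit
        rng = np.random.default_rng(4)
        p = np.clip(rng.beta(2, 2, 20_000), 1e-3, 1 - 1e-3)
        y = (rng.random(20_000) < expit(logit(p) + 0.8)).astype(float)
        curve = fit_flexible_curve(p, y)
        inner = (curve.grid > 0.1) & (curve.grid < 0.9)
        assert np.mean(curve.observed[inner] > curve.grid[inner]) > 0.95


class TestAverageCenterCurves:
    def test_single_curve_unchanged(self):
        c = constant_curve(0.3)
        assert average_center_curves([c]) is c

    def test_equal_weights_mean(self):
        pooled = average_center_curves([constant_curve(0.2, n=100),
                                        constant_curve(0.6, n=100)])
        assert np.allclose(pooled.observed, 0.4)

    def test_sqrt_n_weights(self):
        # n=100 and n=400: weights 10 and 20 -> (10*0 + 20*0.3)/30 = 0.2
        pooled = average_center_curves([constant_curve(0.0, n=100),
                                        constant_curve(0.3, n=400)])
        assert np.allclose(pooled.observed, 0.2)

    def test_pooled_curve_between_ordered_center_curves(self):
        rng = np.random.default_rng(5)
        grid = np.linspace(0, 1, 50)
        lo = CalibrationCurve("benign", grid, np.clip(grid - 0.1, 0, 1), n=150)
        hi = CalibrationCurve("benign", grid, np.clip(grid + 0.1, 0, 1), n=350)
        pooled = average_center_curves([lo, hi])
        lo_i = np.interp(pooled.grid, lo.grid, lo.observed)
        hi_i = np.interp(pooled.grid, hi.grid, hi.observed)
        assert np.all(pooled.observed >= lo_i - 1e-12)
        assert np.all(pooled.observed <= hi_i + 1e-12)

    def test_incompatible_categories_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            average_center_curves([constant_curve(0.2, "benign"),
                                   constant_curve(0.2, "borderline")])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_center_curves([])


class TestRescaledEci:
    def test_diagonal_curve_gives_zero(self):
        rng = np.random.default_rng(6)
        p = rng.random(500)
        y = (rng.random(500) < p).astype(float)
        grid = np.linspace(0, 1, 11)
        diagonal = CalibrationCurve("benign", grid, grid)
        assert rescaled_eci(p, y, diagonal) == 0.0

    def test_horizontal_curve_gives_one(self):
        rng = np.random.default_rng(7)
        p = rng.random(500)
        y = (rng.random(500) < 0.5).astype(float)
        horizontal = constant_curve(y.mean())
        assert rescaled_eci(p, y, horizontal) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_value(self):
        # c(p) = p + 0.1, ybar = 0.5: raw = 0.01,
        # denom = mean((p-0.5)^2) = 0.05, rescaled = 0.2
        p = np.array([0.2, 0.4, 0.6, 0.8])
        y = np.array([0.0, 1.0, 0.0, 1.0])  # ybar = 0.5
        grid = np.linspace(0, 1, 101)
        curve = CalibrationCurve("benign", grid, np.clip(grid + 0.1, 0, 1))
        assert rescaled_eci(p, y, curve) == pytest.approx(0.2, abs=1e-12)

    def test_zero_denominator_rejected(self):
        p = np.full(100, 0.5)
        y = np.r_[np.ones(50), np.zeros(50)]
        with pytest.raises(ValueError, match="undefined"):
            rescaled_eci(p, y, constant_curve(0.5))

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(8)
        p = rng.random(300)
        y = (rng.random(300) < p).astype(float)
        curve = fit_flexible_curve(p, y)
        perm = rng.permutation(300)
        assert rescaled_eci(p, y, curve) == pytest.approx(
            rescaled_eci(p[perm], y[perm], curve), abs=1e-12)


class TestMulticlassEci:
    def _simulate(self, n, calibrated, seed):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet([2, 1, 1, 1, 1], n)
        if calibrated:
            u = rng.random(n)
            y = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
        else:
            y = rng.choice(5, size=n, p=[0.6, 0.1, 0.1, 0.15, 0.05])
        return P, y

    def test_perfect_calibration_near_zero(self):
        P, y = self._simulate(60_000, True, 9)
        centers = np.repeat([1, 2, 3], 20_000)
        curves = pooled_calibration_curves(P, y, centers)
        res = multiclass_eci(P, y, curves)
        assert np.all(res.per_category_eci <= 0.02)

    def test_outcome_independent_predictions_near_one(self):
        P, y = self._simulate(60_000, False, 10)
        centers = np.repeat([1, 2, 3], 20_000)
        curves = pooled_calibration_curves(P, y, centers)
        res = multiclass_eci(P, y, curves)
        assert np.all(np.abs(res.per_category_eci - 1.0) < 0.05)

    def test_mean_is_average_of_components(self):
        P, y = self._simulate(5000, True, 11)
        curves = pooled_calibration_curves(P, y, np.ones(5000, int))
        res = multiclass_eci(P, y, curves)
        assert res.mean_eci == pytest.approx(res.per_category_eci.mean(), abs=1e-12)

    def test_missing_curve_rejected(self):
        P, y = self._simulate(1000, True, 12)
        with pytest.raises(ValueError, match=OUTCOME_LEVELS[1]):
            multiclass_eci(P, y, {"benign": constant_curve(0.5)})
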