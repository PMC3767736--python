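"""Seasonal Gompertz dynamics: means, densities, classification, fixed points."""

import numpy as np
import pytest

from spotnmix import (
    BREEDING,
    NONBREEDING,
    ProcessParams,
    classify_density_dependence,
    gompertz_mean_predator,
    gompertz_mean_prey,
    process_loglik,
    seasonal_fixed_point,
)


class TestGompertzMeans:
    def test_random_walk_limit(self):
        # b = 1, a = 0: no density dependence, mean equals the current state
        p = ProcessParams(a_b=0.0, a_nb=0.0, b=1.0, sigma=0.1)
        for x in (-2.0, 0.0, 3.7):
            assert gompertz_mean_prey(x, BREEDING, p) == pytest.approx(x)

    def test_nonbreeding_intercept_arithmetic(self):
        p = ProcessParams(a_b=1.19, a_nb=1.98, b=0.5, sigma=0.1)
        assert gompertz_mean_prey(2.0, NONBREEDING, p) == pytest.approx(2.98)

    def test_full_regulation_to_intercept(self):
        p = ProcessParams(a_b=0.7, a_nb=0.7, b=0.0, sigma=0.1)
        assert gompertz_mean_prey(123.0, BREEDING, p) == pytest.approx(0.7)

    def test_predator_reduces_to_prey_when_uncoupled(self):
        p = ProcessParams(a_b=0.4, a_nb=-0.2, b=0.8, sigma=0.1, c_b=0.0, c_nb=0.0)
        for st in (BREEDING, NONBREEDING):
            assert gompertz_mean_predator(1.3, 5.0, st, p) == pytest.approx(
                gompertz_mean_prey(1.3, st, p))

    def test_predator_lagged_prey_arithmetic(self):
        p = ProcessParams(a_b=0.0, a_nb=0.0, b=0.5, sigma=0.1, c_b=0.0, c_nb=0.4)
        assert gompertz_mean_predator(1.0, 3.0, NONBREEDING, p) == pytest.approx(1.7)

    def test_zero_state(self):
        p = ProcessParams(a_b=0.3, a_nb=0.3, b=0.9, sigma=0.1, c_b=0.5, c_nb=0.5)
        assert gompertz_mean_predator(0.0, 0.0, BREEDING, p) == pytest.approx(0.3)

    def test_predator_slope_in_log_prey_is_c(self):
        # finite-difference check that the lagged-prey slope equals c_season
        p = ProcessParams(a_b=0.2, a_nb=-0.1, b=0.7, sigma=0.1, c_b=0.15, c_nb=0.6)
        h = 1e-6
        for st, c in ((BREEDING, 0.15), (NONBREEDING, 0.6)):
            d = (gompertz_mean_predator(1.0, 2.0 + h, st, p)
                 - gompertz_mean_predator(1.0, 2.0, st, p)) / h
            assert d == pytest.approx(c, abs=1e-5)


class TestProcessLoglik:
    def test_mode_value(self):
        s = 0.73
        assert process_loglik(1.4, 1.4, s) == pytest.approx(
            -np.log(s * np.sqrt(2 * np.pi)))

    def test_standard_normal_at_one(self):
        # -log(sqrt(2*pi)) - 1/2 = -1.4189385 (scipy.stats.norm oracle)
        assert process_loglik(0.0, 1.0, 1.0) == pytest.approx(-1.4189385,
                                                              abs=1e-6)

    def test_sigma_zero_is_degenerate(self):
        with pytest.raises(ValueError):
            process_loglik(0.0, 0.1, 0.0)

    def test_tiny_sigma_far_from_mean_diverges(self):
        assert process_loglik(0.0, 1.0, 1e-8) < -1e10

    def test_integrates_to_one(self):
        from scipy.integrate import quad
        val, _ = quad(lambda x: np.exp(process_loglik(x, 0.7, 0.9)), -12, 12)
        assert val == pytest.approx(1.0, abs=1e-8)


class TestClassifyDensityDependence:
    @pytest.mark.parametrize("b, label", [
        (1.0, "none"),
        (0.5, "negative"),
        (-0.3, "positive"),
    ])
    def test_labels(self, b, label):
        assert classify_density_dependence(b) == label

    def test_other_carries_value(self):
        assert "1.5" in classify_density_dependence(1.5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_density_dependence(np.nan)


class TestSeasonalFixedPoint:
    def test_iteration_converges_to_closed_form(self):
        # deterministic two-season map, 0 < b < 1: geometric convergence
        p = ProcessParams(a_b=1.19, a_nb=1.98, b=0.6, sigma=0.0)
        x = 0.0
        seasons = [BREEDING, NONBREEDING] * 200
        for st in seasons:
            x = gompertz_mean_prey(x, st, p)
        # after an even number of steps the state sits at the value attained
        # in the last-applied season (non-breeding here)
        x_nb, _ = seasonal_fixed_point(p, first_season=NONBREEDING)
        assert x == pytest.approx(x_nb, abs=1e-10)

    def test_fixed_point_is_invariant(self):
        p = ProcessParams(a_b=0.8, a_nb=-0.3, b=0.45, sigma=0.0)
        x_b, x_nb = seasonal_fixed_point(p, first_season=BREEDING)
        assert gompertz_mean_prey(x_nb, BREEDING, p) == pytest.approx(x_b)
        assert gompertz_mean_prey(x_b, NONBREEDING, p) == pytest.approx(x_nb)

    def test_unit_b_has_no_fixed_point(self):
        with pytest.raises(ValueError):
            seasonal_fixed_point(ProcessParams(b=1.0))
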