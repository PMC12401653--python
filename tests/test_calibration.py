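"""Weighted calibration fitting, Mandel test, weighting selection and
back-calculation acceptance, each checked against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxscreen import (AcceptanceThresholds, CalPoint, backcalc_check,
                       fit_weighted_linear, mandel_test, select_weighting)
from toxscreen.calibration import heteroscedasticity_ftest

from conftest import ALPRAZOLAM_LEVELS, noisy_curve

WEIGHTS = {"equal": lambda x, y: np.ones_like(x),
           "1/x": lambda x, y: 1 / x,
           "1/x2": lambda x, y: 1 / x**2,
           "1/y": lambda x, y: 1 / y,
           "1/y2": lambda x, y: 1 / y**2}


def wls_normal_equations(points, label):
    """Brute-force WLS oracle: solve the 2x2 weighted normal equations."""
    x = np.array([p.conc for p in points])
    y = np.array([p.ratio for p in points])
    w = WEIGHTS[label](x, y)
    sw, swx, swx2 = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    a, b = np.linalg.solve([[swx2, swx], [swx, sw]], [swxy, swy])
    return a, b


class TestWeightedFit:
    @pytest.mark.parametrize("label", list(WEIGHTS))
    def test_noiseless_line_is_weighting_invariant(self, label,
                                                   exact_line_points):
        fit = fit_weighted_linear(exact_line_points, label)
        assert fit.slope == pytest.approx(0.002, rel=1e-12)
        assert fit.intercept == pytest.approx(0.01, rel=1e-9)
        assert fit.ssr_relative == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("label", list(WEIGHTS))
    def test_matches_normal_equations_oracle(self, label, rng):
        # 100 random 5-point sets per label, 1e-10 relative agreement
        for _ in range(100):
            pts = noisy_curve(ALPRAZOLAM_LEVELS, slope=0.002,
                              intercept=0.01, prop_sd=0.05 * 0.002,
                              const_sd=1e-4, rng=rng)
            fit = fit_weighted_linear(pts, label)
            a, b = wls_normal_equations(pts, label)
            assert fit.slope == pytest.approx(a, rel=1e-10)
            assert fit.intercept == pytest.approx(b, rel=1e-10, abs=1e-14)

    def test_panel_weighting_labels_accepted(self, exact_line_points):
        for raw in ("1/x^2", "Equal"):
            fit = fit_weighted_linear(exact_line_points, raw)
            assert fit.slope == pytest.approx(0.002)

    def test_equal_weights_reproduce_ols(self, rng):
        pts = noisy_curve(ALPRAZOLAM_LEVELS, 0.002, 0.01,
                          prop_sd=0.0, const_sd=0.02, rng=rng)
        fit = fit_weighted_linear(pts, "equal")
        x = np.array([p.conc for p in pts])
        y = np.array([p.ratio for p in pts])
        slope_ols, intercept_ols = np.linalg.lstsq(
            np.column_stack([x, np.ones_like(x)]), y, rcond=None)[0]
        assert fit.slope == pytest.approx(slope_ols, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept_ols, rel=1e-12)

    def test_point_on_line_leaves_fit_unchanged(self, rng):
        pts = noisy_curve(ALPRAZOLAM_LEVELS, 0.002, 0.01,
                          prop_sd=0.0, const_sd=0.01, rng=rng)
        fit = fit_weighted_linear(pts, "1/x")
        extra = CalPoint(800.0, fit.slope * 800.0 + fit.intercept)
        refit = fit_weighted_linear([*pts, extra], "1/x")
        assert refit.slope == pytest.approx(fit.slope, rel=1e-12)
        assert refit.intercept == pytest.approx(fit.intercept, rel=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_weighted_linear([CalPoint(1, 1), CalPoint(2, 2)], "equal")

    def test_singular_design_rejected(self):
        pts = [CalPoint(100, 0.1), CalPoint(100, 0.2), CalPoint(100, 0.3)]
        with pytest.raises(ValueError, match="singular"):
            fit_weighted_linear(pts, "equal")

    def test_zero_ratio_under_inverse_y_rejected(self):
        pts = [CalPoint(100, 0.0), CalPoint(500, 1.0), CalPoint(1000, 2.0)]
        with pytest.raises(ValueError, match="positive ratios"):
            fit_weighted_linear(pts, "1/y2")

    def test_slope_recovery_under_proportional_noise(self):
        # median recovered slope within 5% of truth over 200 seeds
        truth = 0.002
        recovered = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            pts = noisy_curve(ALPRAZOLAM_LEVELS, truth, 0.0,
                              prop_sd=0.02 * truth, const_sd=0.0, rng=r)
            recovered.append(fit_weighted_linear(pts, "1/x2").slope)
        median = float(np.median(recovered))
        assert abs(median - truth) / truth < 0.05


class TestMandel:
    def test_linear_data_accepted(self, rng):
        x = np.array([100, 400, 800, 1200, 1600, 2000], float)
        pts = [CalPoint(xi, 0.002 * xi + 0.01 + rng.normal(0, 1e-3))
               for xi in x]
        res = mandel_test(pts, alpha=0.05)
        assert res.linear_accepted
        assert res.sse_quadratic <= res.sse_linear

    def test_exact_quadratic_rejected(self):
        pts = [CalPoint(float(x), float(x) ** 2) for x in range(1, 7)]
        res = mandel_test(pts)
        assert res.sse_quadratic == pytest.approx(0.0, abs=1e-6)
        assert not res.linear_accepted
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_f_statistic_matches_direct_sse_oracle(self):
        # fixed mildly curved 6-point set; oracle fits both polynomials
        # explicitly and applies the variance-ratio formula
        x = np.array([100.0, 400.0, 800.0, 1200.0, 1600.0, 2000.0])
        y = 0.002 * x + 0.01 + 5e-8 * x**2
        y += np.array([1e-3, -2e-3, 1.5e-3, -1e-3, 5e-4, -5e-4])
        pts = [CalPoint(xi, yi) for xi, yi in zip(x, y)]
        res = mandel_test(pts)
        sse1 = float(np.sum((y - np.polyval(np.polyfit(x, y, 1), x)) ** 2))
        sse2 = float(np.sum((y - np.polyval(np.polyfit(x, y, 2), x)) ** 2))
        f_expected = (sse1 - sse2) / (sse2 / (len(x) - 3))
        assert res.f_statistic == pytest.approx(f_expected, rel=1e-9)
        assert res.f_statistic >= 0

    def test_low_power_warning_for_five_calibrators(self, rng):
        pts = noisy_curve(ALPRAZOLAM_LEVELS, 0.002, 0.0,
                          prop_sd=0.0, const_sd=1e-3, rng=rng)
        with pytest.warns(UserWarning, match="low power"):
            mandel_test(pts)

    def test_insufficient_points_rejected(self):
        pts = [CalPoint(1, 1), CalPoint(2, 2), CalPoint(3, 3)]
        with pytest.raises(ValueError, match="at least 4"):
            mandel_test(pts)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-0.01, 0.01), min_size=6, max_size=6),
           st.floats(1e-4, 1e-2))
    def test_nesting_invariant(self, noise, slope):
        # quadratic SSE never exceeds linear SSE; F and p well-defined
        x = [100.0, 400.0, 800.0, 1200.0, 1600.0, 2000.0]
        pts = [CalPoint(xi, slope * xi + n) for xi, n in zip(x, noise)]
        res = mandel_test(pts)
        assert res.sse_quadratic <= res.sse_linear
        assert res.f_statistic >= 0
        assert 0.0 <= res.p_value <= 1.0


class TestWeightingSelection:
    def test_noiseless_tie_breaks_to_equal(self, exact_line_points):
        sel = select_weighting([exact_line_points, exact_line_points,
                                exact_line_points])
        assert sel.label == "equal"
        assert all(t == pytest.approx(0.0, abs=1e-18)
                   for t in sel.total_ssr.values())

    def test_proportional_noise_prefers_inverse_x_family(self):
        # 100 seeds, noise sd = 0.05*conc on the ratio scale
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            curves = [noisy_curve(ALPRAZOLAM_LEVELS, 0.002, 0.01,
                                  prop_sd=0.05 * 0.002, const_sd=0.0,
                                  rng=r)
                      for _ in range(3)]
            if select_weighting(curves).label in ("1/x", "1/x2"):
                wins += 1
        assert wins >= 90

    def test_constant_noise_keeps_equal_weighting(self):
        # homoscedastic scatter: the variance gate retains equal weighting
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            curves = [noisy_curve(ALPRAZOLAM_LEVELS, 0.002, 0.01,
                                  prop_sd=0.0, const_sd=2e-4, rng=r)
                      for _ in range(3)]
            if select_weighting(curves).label == "equal":
                wins += 1
        assert wins >= 90

    def test_relative_ssr_criterion_available(self, rng):
        curves = [noisy_curve(ALPRAZOLAM_LEVELS, 0.002, 0.01,
                              prop_sd=0.0, const_sd=2e-4, rng=rng)
                  for _ in range(3)]
        sel = select_weighting(curves, criterion="relative_ssr")
        # relative errors concentrate at the lowest calibrators, so this
        # criterion prefers a weighted label even for constant noise
        assert sel.label != "equal"

    def test_output_domain_is_the_five_labels(self, rng):
        curves = [noisy_curve(ALPRAZOLAM_LEVELS, 0.002, 0.01,
                              prop_sd=1e-4, const_sd=1e-4, rng=rng)
                  for _ in range(3)]
        sel = select_weighting(curves)
        assert set(sel.total_ssr) == {"equal", "1/x", "1/x2", "1/y", "1/y2"}
        assert sel.label in sel.total_ssr

    def test_unfittable_label_excluded_with_warning(self, rng):
        good = noisy_curve(ALPRAZOLAM_LEVELS, 0.002, 0.0,
                           prop_sd=0.0, const_sd=1e-5, rng=rng)
        with_zero = [*good[:-1], CalPoint(500.0, 0.0)]
        with pytest.warns(UserWarning, match="excluded"):
            sel = select_weighting([good, with_zero])
        assert set(sel.excluded) == {"1/y", "1/y2"}
        assert sel.label in ("equal", "1/x", "1/x2")

    def test_single_replicate_rejected(self, exact_line_points):
        with pytest.raises(ValueError, match="2 replicate"):
            select_weighting([exact_line_points])


class TestBackcalc:
    def _fit_identity(self):
        # slope 1, intercept 0: ratios == concentrations, bias injectable
        pts = [CalPoint(x, x) for x in ALPRAZOLAM_LEVELS]
        return fit_weighted_linear(pts, "equal")

    def _points_with_bias(self, bias_pct_by_level):
        return [CalPoint(x, x * (1 + b / 100.0))
                for x, b in zip(ALPRAZOLAM_LEVELS, bias_pct_by_level)]

    def test_five_point_rule_requires_four(self):
        fit = self._fit_identity()
        report = backcalc_check(fit, self._points_with_bias([0, 0, 0, 0, 0]),
                                lloq=50.0)
        assert report.min_required == 4  # ceil(0.75 * 5)

    def test_one_failing_mid_level_still_passes(self):
        fit = self._fit_identity()
        report = backcalc_check(
            fit, self._points_with_bias([0, 0, 18, 0, 0]), lloq=50.0)
        assert report.n_pass == 4
        assert report.overall_pass

    def test_all_exact_passes(self):
        fit = self._fit_identity()
        report = backcalc_check(
            fit, self._points_with_bias([0, 0, 0, 0, 0]), lloq=50.0)
        assert report.n_pass == 5 and report.overall_pass

    def test_two_failing_mid_levels_fail(self):
        fit = self._fit_identity()
        report = backcalc_check(
            fit, self._points_with_bias([0, 16, -16, 0, 0]), lloq=50.0)
        assert report.n_pass == 3
        assert not report.overall_pass

    def test_lloq_gets_wider_limit(self):
        fit = self._fit_identity()
        # +18% at the LLOQ level passes (limit 20%), +18% elsewhere fails
        report = backcalc_check(
            fit, self._points_with_bias([18, 0, 0, 0, 0]), lloq=50.0)
        assert report.per_level_pass[0]
        report2 = backcalc_check(
            fit, self._points_with_bias([0, 18, 0, 0, 0]), lloq=50.0)
        assert not report2.per_level_pass[1]

    def test_bias_values_are_exact(self):
        fit = self._fit_identity()
        report = backcalc_check(
            fit, self._points_with_bias([5, -10, 18, 0, -2]), lloq=50.0)
        assert report.per_level_bias_pct == pytest.approx(
            (5, -10, 18, 0, -2), abs=1e-9)


class TestHeteroscedasticity:
    def test_proportional_noise_flagged(self):
        r = np.random.default_rng(7)
        curves = [noisy_curve(ALPRAZOLAM_LEVELS, 0.002, 0.0,
                              prop_sd=0.10 * 0.002, const_sd=0.0, rng=r)
                  for _ in range(12)]
        f_stat, p = heteroscedasticity_ftest(curves)
        assert f_stat > 1.0
        assert p < 0.05
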