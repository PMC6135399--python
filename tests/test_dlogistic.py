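"""Double-logistic model evaluation, fitting, and coefficient-table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chiagrow import (
    BIOMASS_COEFFICIENTS,
    LEAF_AREA_COEFFICIENTS,
    DoubleLogisticCoefficients,
    average_coefficients,
    compare_fits,
    double_logistic,
    double_logistic_derivative,
    fit_double_logistic,
    goodness_of_fit,
    initial_guess,
)

GRID = np.arange(0.0, 1401.0, 25.0)


def coef(**kw):
    base = dict(y_min=0.0, y_max=30.0, m_s=0.01, s=500.0, m_a=0.02, a=1000.0)
    base.update(kw)
    return DoubleLogisticCoefficients(**base)


def test_logistic_half_at_growth_inflection():
    c = coef(y_min=0.0, y_max=10.0, m_a=1e-3, a=1e7)
    # second sigmoid pinned at 1; first contributes exactly 0.5 at t = s
    assert double_logistic(c.s, c) == pytest.approx(10.0 * 1.5)


def test_constant_when_range_is_zero():
    c = coef(y_min=5.0, y_max=5.0)
    t = np.linspace(-100, 2000, 50)
    np.testing.assert_allclose(double_logistic(t, c), 5.0)
    np.testing.assert_allclose(double_logistic_derivative(t, c), 0.0)


def test_sd1_row_at_zero_matches_hand_evaluation():
    """Published SD1 coefficients at t=0 vs direct two-exponential arithmetic."""
    c = DoubleLogisticCoefficients.from_row(BIOMASS_COEFFICIENTS.loc["SD1"])
    term1 = 1.0 / (1.0 + np.exp(-c.m_s * (0.0 - c.s)))
    term2 = 1.0 / (1.0 + np.exp(c.m_a * (0.0 - c.a)))
    expected = c.y_min + (c.y_max - c.y_min) * (term1 + term2)
    assert double_logistic(0.0, c) == pytest.approx(expected, rel=1e-12)


def test_extreme_exponents_are_safe():
    c = coef(m_s=1.0, s=0.0, m_a=1.0, a=10.0)
    v = double_logistic(np.array([-1e6, 1e6]), c)
    assert np.isfinite(v).all()


def test_derivative_matches_finite_difference(rng):
    c = DoubleLogisticCoefficients.from_row(BIOMASS_COEFFICIENTS.loc["IT1"])
    for t in rng.uniform(0, 1400, 20):
        h = 1e-3
        fd = (double_logistic(t + h, c) - double_logistic(t - h, c)) / (2 * h)
        assert double_logistic_derivative(t, c) == pytest.approx(fd, rel=1e-6, abs=1e-10)


def test_derivative_sign_changes_bounded():
    """A sum of two sigmoids has at most two slope sign changes."""
    c = DoubleLogisticCoefficients.from_row(BIOMASS_COEFFICIENTS.loc["SD1"])
    d = double_logistic_derivative(np.linspace(0, 1500, 2000), c)
    signs = np.sign(d[np.abs(d) > 1e-14])
    changes = int((np.diff(signs) != 0).sum())
    assert changes <= 2


def test_initial_guess_order_invariance(rng):
    c = coef()
    t = np.linspace(0, 1400, 30)
    y = double_logistic(t, c)
    g1 = initial_guess(t, y)
    perm = rng.permutation(len(t))
    g2 = initial_guess(t[perm], y[perm])
    np.testing.assert_allclose(g1.as_array(), g2.as_array())


def test_initial_guess_constant_series_errors():
    with pytest.raises(ValueError):
        initial_guess([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])


def test_initial_guess_monotone_series_flags_a():
    t = np.linspace(0, 800, 20)
    y = 1.0 / (1.0 + np.exp(-0.01 * (t - 400)))  # still rising at the end
    with pytest.warns(UserWarning, match="defaulted"):
        g = initial_guess(t, y)
    assert g.a == t[-1]


@pytest.mark.parametrize("row", ["SD1", "SD2", "IT1", "IT2"])
def test_zero_noise_fixed_point_recovery(row):
    """Noise-free data from a published row is a zero-residual fixed point."""
    c = DoubleLogisticCoefficients.from_row(BIOMASS_COEFFICIENTS.loc[row])
    y = double_logistic(GRID, c)
    fit = fit_double_logistic(GRID, y, init=c, restarts=0)
    np.testing.assert_allclose(fit.coefficients.as_array(), c.as_array(), rtol=1e-6)
    assert fit.sse < 1e-12
    assert fit.converged


@pytest.mark.parametrize("row", ["SD1", "IT2"])
def test_zero_noise_recovery_from_heuristic_start(row):
    """The heuristic start and restarts find the generating coefficients."""
    c = DoubleLogisticCoefficients.from_row(BIOMASS_COEFFICIENTS.loc[row])
    y = double_logistic(GRID, c)
    fit = fit_double_logistic(GRID, y, restarts=8, seed=0)
    np.testing.assert_allclose(fit.coefficients.as_array(), c.as_array(), rtol=1e-6)


def test_noisy_sd1_fit_reaches_published_determination(sd1_biomass):
    """Gaussian noise at the published residual scale still gives R^2 > 0.98."""
    rng = np.random.default_rng(5)
    y = double_logistic(GRID, sd1_biomass) + rng.normal(0, 0.4906, GRID.size)
    fit = fit_double_logistic(GRID, y, restarts=8, seed=1)
    assert fit.r2 > 0.98
    assert abs(fit.coefficients.s - sd1_biomass.s) / sd1_biomass.s < 0.02


def test_lm_beats_coarse_grid_search(sd1_biomass):
    """LM solution SSE <= the best node of a coarse lattice around the optimum."""
    rng = np.random.default_rng(11)
    y = double_logistic(GRID, sd1_biomass) + rng.normal(0, 0.5, GRID.size)
    fit = fit_double_logistic(GRID, y, restarts=8, seed=2)
    truth = sd1_biomass.as_array()
    best_grid = np.inf
    for scale in (0.9, 0.95, 1.0, 1.05, 1.1):
        cand = DoubleLogisticCoefficients.from_array(truth * scale)
        sse = float(np.sum((double_logistic(GRID, cand) - y) ** 2))
        best_grid = min(best_grid, sse)
    assert fit.sse <= best_grid + 1e-9


def test_sse_not_worse_than_initial_guess(sd1_biomass):
    rng = np.random.default_rng(21)
    y = double_logistic(GRID, sd1_biomass) + rng.normal(0, 1.0, GRID.size)
    g = initial_guess(GRID, y)
    sse_guess = float(np.sum((double_logistic(GRID, g) - y) ** 2))
    fit = fit_double_logistic(GRID, y, init=g, restarts=5, seed=3)
    assert fit.sse <= sse_guess + 1e-9


def test_fit_requires_seven_distinct_points():
    with pytest.raises(ValueError):
        fit_double_logistic([0, 1, 2, 3, 4, 5], [1, 2, 3, 4, 5, 6])


def test_goodness_of_fit_limits():
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    rmse, error, r2, p = goodness_of_fit(y, y)
    assert rmse == 0.0 and r2 == 1.0 and p == 0.0
    rmse, error, r2, p = goodness_of_fit(y, np.full_like(y, y.mean()))
    assert r2 == pytest.approx(0.0)


def test_goodness_of_fit_formula_recomputation(rng):
    y = rng.normal(10, 3, 20)
    yhat = y + rng.normal(0, 1, 20)
    rmse, error, r2, p = goodness_of_fit(y, yhat)
    sse = np.sum((y - yhat) ** 2)
    sst = np.sum((y - y.mean()) ** 2)
    assert rmse == pytest.approx(np.sqrt(sse / 20), rel=1e-12)
    assert error == pytest.approx(np.sqrt(sse / 14), rel=1e-12)
    assert r2 == pytest.approx(1 - sse / sst, rel=1e-12)
    f = ((sst - sse) / 5) / (sse / 14)
    assert p == pytest.approx(stats.f.sf(f, 5, 14), rel=1e-9)
    # rmse^2 * n == error^2 * (n - 6) exactly
    assert rmse**2 * 20 == pytest.approx(error**2 * 14, rel=1e-12)


def test_goodness_of_fit_needs_more_points_than_params():
    with pytest.raises(ValueError):
        goodness_of_fit([1, 2, 3], [1, 2, 3])


def test_average_rows_match_published_summary():
    """Element-wise means reproduce the published average rows to 3 decimals."""
    avg_sd = average_coefficients(BIOMASS_COEFFICIENTS.loc[["SD1", "SD2"]])
    assert avg_sd["y_max"] == pytest.approx(84.754, abs=5.0001e-4)
    assert avg_sd["y_min"] == pytest.approx(-85.794, abs=5.0001e-4)
    avg_it = average_coefficients(LEAF_AREA_COEFFICIENTS.loc[["IT1", "IT2"]])
    assert avg_it["a"] == pytest.approx(669.096, abs=5.0001e-4)


def test_average_single_row_is_itself():
    row = BIOMASS_COEFFICIENTS.loc[["IT1"]]
    avg = average_coefficients(row)
    pd.testing.assert_series_equal(avg, row.iloc[0], check_names=False)


def test_average_empty_errors():
    with pytest.raises(ValueError):
        average_coefficients([])


def _converged_fit(c):
    y = double_logistic(GRID, c)
    return fit_double_logistic(GRID, y, init=c, restarts=0)


def test_compare_identical_fits_p_one(sd1_biomass):
    fit = _converged_fit(sd1_biomass)
    assert compare_fits(fit, fit) == 1.0


def test_compare_fits_shift_vs_closed_form(sd1_biomass):
    """A noisy coefficient shift reproduces the closed-form paired t."""
    fit_a = _converged_fit(sd1_biomass)
    shifted = DoubleLogisticCoefficients.from_array(
        sd1_biomass.as_array() + np.array([5.0, 6.0, 4.5, 5.5, 5.2, 4.8])
    )
    fit_b = _converged_fit(shifted)
    d = fit_a.coefficients.as_array() - fit_b.coefficients.as_array()
    tstat = d.mean() / (d.std(ddof=1) / np.sqrt(6))
    expected = 2 * stats.t.sf(abs(tstat), 5)
    assert compare_fits(fit_a, fit_b) == pytest.approx(expected, rel=1e-6)
    assert compare_fits(fit_a, fit_b) < 0.05


def test_compare_published_sowing_rows_not_significant():
    """SD1 vs SD2 published rows: the difference is declared non-significant."""
    a = BIOMASS_COEFFICIENTS.loc["SD1", ["y_min", "y_max", "m_s", "s", "m_a", "a"]]
    b = BIOMASS_COEFFICIENTS.loc["SD2", ["y_min", "y_max", "m_s", "s", "m_a", "a"]]
    p = stats.ttest_rel(a.to_numpy(float), b.to_numpy(float)).pvalue
    assert p > 0.05


def test_compare_fits_requires_convergence(sd1_biomass):
    fit = _converged_fit(sd1_biomass)
    bad = _converged_fit(sd1_biomass)
    bad.converged = False
    with pytest.raises(ValueError):
        compare_fits(fit, bad)
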