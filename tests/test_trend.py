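"""Trend-fitting: OLS lines, parabolas, log-linear exponentials, standard curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rumengrad import (
    StandardCurve,
    TrendModel,
    fit_exponential,
    fit_linear,
    fit_quadratic,
    invert_standard_curve,
    predict,
    select_family,
)
from rumengrad.reference import (
    ACETATE_PROPORTION,
    CONCENTRATE_FRACTIONS,
    DIET_NUTRIENTS,
    NH3N_STANDARD_CURVE,
    SPIROCHAETES_ABUNDANCE,
)


def ols_oracle(x, y):
    """Independent closed-form normal-equation OLS (slope, intercept, r2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r2 = 1.0 if syy == 0 else sxy**2 / (sxx * syy)
    return slope, intercept, r2


class TestFitLinear:
    def test_acetate_vs_ndf_matches_reported_equation(self):
        m = fit_linear(DIET_NUTRIENTS.loc["ndf"], ACETATE_PROPORTION)
        assert round(m.params["slope"], 4) == 0.0012
        assert round(m.params["intercept"], 3) == 0.641
        assert round(m.r2, 4) == 0.8880

    def test_acetate_vs_nfc_matches_reported_equation(self):
        m = fit_linear(DIET_NUTRIENTS.loc["nfc"], ACETATE_PROPORTION)
        assert round(m.params["slope"], 4) == -0.0017
        assert round(m.params["intercept"], 4) == 0.7545
        assert round(m.r2, 4) == 0.8886

    def test_perfect_line(self):
        m = fit_linear([0, 1], [0, 1])
        assert m.params["slope"] == pytest.approx(1.0)
        assert m.params["intercept"] == pytest.approx(0.0, abs=1e-15)
        assert m.r2 == pytest.approx(1.0)

    def test_constant_y_gives_r2_one(self):
        m = fit_linear([0.0, 1.0, 2.0], [3.3, 3.3, 3.3])
        assert m.params["slope"] == 0.0
        assert m.params["intercept"] == 3.3
        assert m.r2 == 1.0

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear([1.0, 1.0, 1.0], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1.0], [2.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x = rng.normal(0, 3, n)
        while np.ptp(x) == 0:
            x = rng.normal(0, 3, n)
        y = rng.normal(0, 5, n)
        m = fit_linear(x, y)
        slope, intercept, r2 = ols_oracle(x, y)
        assert m.params["slope"] == pytest.approx(slope, abs=1e-10, rel=1e-10)
        assert m.params["intercept"] == pytest.approx(intercept, abs=1e-10, rel=1e-10)
        assert m.r2 == pytest.approx(r2, abs=1e-10)

    def test_r2_invariant_under_affine_x_rescale(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = 2 * x + rng.normal(size=12)
        r2_a = fit_linear(x, y).r2
        r2_b = fit_linear(3.7 * x - 11.0, y).r2
        assert r2_a == pytest.approx(r2_b, abs=1e-12)

    def test_line_passes_through_mean(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 8)
        y = rng.uniform(0, 1, 8)
        m = fit_linear(x, y)
        assert predict(m, x.mean()) == pytest.approx(y.mean(), abs=1e-12)


class TestFitExponential:
    def test_spirochaetes_matches_reported_equation(self):
        m = fit_exponential(list(CONCENTRATE_FRACTIONS), SPIROCHAETES_ABUNDANCE)
        assert round(m.params["k"], 3) == 4.156
        assert round(m.params["a"], 4) == 0.0007

    def test_noiseless_recovery(self):
        x = np.linspace(0, 1, 7)
        y = 0.31 * np.exp(2.5 * x)
        m = fit_exponential(x, y)
        assert m.params["a"] == pytest.approx(0.31, rel=1e-12)
        assert m.params["k"] == pytest.approx(2.5, rel=1e-12)
        assert m.r2 == pytest.approx(1.0)

    def test_is_loglinear_ols_bit_for_bit(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 10)
        y = np.exp(rng.normal(0, 1, 10))
        expo = fit_exponential(x, y)
        loglin = fit_linear(x, np.log(y))
        assert expo.params["k"] == loglin.params["slope"]
        assert expo.params["a"] == math.exp(loglin.params["intercept"])
        assert expo.r2 == loglin.r2

    def test_nonpositive_y_rejected_with_instruction(self):
        with pytest.raises(ValueError, match="pseudo-abundance"):
            fit_exponential([0.0, 0.5, 1.0], [0.1, 0.0, 0.3])


class TestFitQuadratic:
    def test_pure_parabola(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        m = fit_quadratic(x, x**2)
        assert m.params["b2"] == pytest.approx(1.0, abs=1e-10)
        assert m.params["b1"] == pytest.approx(0.0, abs=1e-10)
        assert m.params["b0"] == pytest.approx(0.0, abs=1e-10)
        assert m.r2 == pytest.approx(1.0)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(-1, 1, 6)
        y = rng.normal(0, 2, 6)
        m = fit_quadratic(x, y)
        design = np.column_stack([x**2, x, np.ones_like(x)])
        coef = np.linalg.pinv(design) @ y
        assert m.params["b2"] == pytest.approx(coef[0], abs=1e-8)
        assert m.params["b1"] == pytest.approx(coef[1], abs=1e-8)
        assert m.params["b0"] == pytest.approx(coef[2], abs=1e-8)

    def test_downward_parabola_sign(self):
        x = np.linspace(0, 1, 9)
        y = -(x - 0.5) ** 2 + 0.3
        m = fit_quadratic(x, y)
        assert m.params["b2"] < 0

    def test_too_few_distinct_x_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic([0.0, 0.0, 1.0], [1, 2, 3])


class TestSelectFamily:
    def test_tie_goes_to_fewest_coefficients(self):
        x = np.linspace(0, 1, 6)
        m = select_family(x, 2 * x + 1, candidates=("linear", "quadratic"))
        assert m.family == "linear"

    def test_exact_exponential_chosen(self):
        x = np.linspace(0, 1, 6)
        m = select_family(x, 0.2 * np.exp(3 * x))
        assert m.family == "exponential"

    def test_zero_y_with_only_exponential_errors(self):
        with pytest.raises(ValueError, match="admissible"):
            select_family([0.0, 0.5, 1.0], [0.0, 0.1, 0.2], candidates=("exponential",))

    def test_comparison_on_original_scale(self):
        # heteroscedastic data engineered so log-scale r2 would flatter
        # the exponential; selection must still use the raw-scale r2
        x = np.array([0.2, 0.35, 0.5, 0.65, 0.8])
        y = np.array([0.0024, 0.0029, 0.0033, 0.0045, 0.0435])
        m = select_family(x, y, candidates=("linear", "quadratic", "exponential"))
        assert m.r2_original >= fit_exponential(x, y).r2_original


class TestPredictAndStandardCurve:
    def test_linear_predict_at_zero_gives_intercept(self):
        m = TrendModel("linear", {"slope": -0.4605, "intercept": 0.8335},
                       0.9582, (0.2, 0.8), 5)
        assert predict(m, 0.0) == 0.8335

    def test_exponential_predict_at_zero_gives_prefactor(self):
        m = TrendModel("exponential", {"a": 0.0007, "k": 4.156}, 0.8, (0.2, 0.8), 5)
        assert predict(m, 0.0) == 0.0007

    def test_zero_concentration_absorbance_is_curve_intercept(self):
        assert invert_standard_curve(0.0157, NH3N_STANDARD_CURVE) == pytest.approx(0.0)

    def test_invert_known_concentration(self):
        # forward: 0.0423*10 + 0.0157 = 0.4387
        assert invert_standard_curve(0.4387, NH3N_STANDARD_CURVE) == pytest.approx(10.0)

    @given(st.floats(0.01, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_invert_is_inverse_of_forward(self, conc):
        absorb = NH3N_STANDARD_CURVE.slope * conc + NH3N_STANDARD_CURVE.intercept
        assert invert_standard_curve(absorb, NH3N_STANDARD_CURVE) == pytest.approx(
            conc, rel=1e-12
        )

    def test_zero_slope_curve_rejected(self):
        with pytest.raises(ValueError):
            StandardCurve(slope=0.0, intercept=0.1)
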