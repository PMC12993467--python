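"""Response-curve fitting along the concentrate gradient.

Three curve families cover the response shapes seen in rumen gradient
studies: straight lines (most fermentation parameters and the core phyla),
downward/upward parabolas (taxa peaking at intermediate diets), and
exponentials (rare taxa that explode at high concentrate, fitted by OLS on
the log scale so the printed ``a * e^(k*x)`` parameterisation is exactly
the back-transformed log-linear fit).

All fits are unweighted ordinary least squares. ``r2`` is reported on the
fitting scale; for family comparison ``select_family`` always recomputes
1 - SSres/SStot on the original y scale so the families compete fairly.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .types import StandardCurve, TrendModel

__all__ = [
    "fit_linear",
    "fit_quadratic",
    "fit_exponential",
    "select_family",
    "predict",
    "r2_original_scale",
    "invert_standard_curve",
]


def _as_xy(x: Iterable[float], y: Iterable[float], min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("x and y must be finite")
    return x, y


def fit_linear(x: Sequence[float], y: Sequence[float]) -> TrendModel:
    """OLS straight line y = slope*x + intercept.

    r2 is the squared Pearson correlation (equivalently 1 - SSres/SStot).
    A constant y (zero total sum of squares) is fitted exactly by the
    horizontal line through it and reported with r2 = 1.
    """
    x, y = _as_xy(x, y, 2)
    if np.ptp(x) == 0:
        raise ValueError("x is constant; a line cannot be identified")
    if np.ptp(y) == 0:
        # degenerate but exactly representable: horizontal line, zero residual
        model = TrendModel(
            family="linear",
            params={"slope": 0.0, "intercept": float(y[0])},
            r2=1.0,
            x_range=(float(x.min()), float(x.max())),
            n=int(x.size),
        )
        model.r2_original = 1.0
        return model
    res = stats.linregress(x, y)
    model = TrendModel(
        family="linear",
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        r2=float(res.rvalue**2),
        x_range=(float(x.min()), float(x.max())),
        n=int(x.size),
    )
    model.r2_original = model.r2
    return model


def fit_quadratic(x: Sequence[float], y: Sequence[float]) -> TrendModel:
    """Least-squares parabola y = b2*x^2 + b1*x + b0."""
    x, y = _as_xy(x, y, 3)
    if np.unique(x).size < 3:
        raise ValueError("quadratic fit needs >= 3 distinct x values")
    b2, b1, b0 = np.polyfit(x, y, 2)
    model = TrendModel(
        family="quadratic",
        params={"b2": float(b2), "b1": float(b1), "b0": float(b0)},
        r2=1.0,  # placeholder, replaced below
        x_range=(float(x.min()), float(x.max())),
        n=int(x.size),
    )
    r2 = r2_original_scale(model, x, y)
    model.r2 = r2
    model.r2_original = r2
    return model


def fit_exponential(x: Sequence[float], y: Sequence[float]) -> TrendModel:
    """Exponential y = a * e^(k*x), fitted as OLS of ln y on x.

    Requires strictly positive y; zeros in compositional data are
    meaningful, so callers must filter or substitute a pseudo-abundance
    explicitly rather than having it done silently here. The stored r2 is
    the log-scale coefficient of determination (the scale on which the fit
    is performed); ``r2_original`` carries 1 - SSres/SStot against
    a*e^(k*x) on the raw scale.
    """
    x, y = _as_xy(x, y, 2)
    if np.any(y <= 0):
        raise ValueError(
            "exponential fit requires all y > 0; filter non-positive values "
            "or substitute an explicit pseudo-abundance first"
        )
    loglin = fit_linear(x, np.log(y))
    model = TrendModel(
        family="exponential",
        params={
            "a": float(np.exp(loglin.params["intercept"])),
            "k": float(loglin.params["slope"]),
        },
        r2=loglin.r2,
        x_range=loglin.x_range,
        n=loglin.n,
    )
    model.r2_original = r2_original_scale(model, x, y)
    return model


def predict(model: TrendModel, x):
    """Evaluate a fitted trend model at x (scalar or array)."""
    x = np.asarray(x, dtype=float)
    p = model.params
    if model.family == "linear":
        out = p["slope"] * x + p["intercept"]
    elif model.family == "quadratic":
        out = p["b2"] * x**2 + p["b1"] * x + p["b0"]
    elif model.family == "exponential":
        out = p["a"] * np.exp(p["k"] * x)
    else:  # pragma: no cover - guarded by TrendModel validation
        raise ValueError(f"unknown family {model.family!r}")
    return out.item() if out.ndim == 0 else out


def r2_original_scale(model: TrendModel, x: Sequence[float], y: Sequence[float]) -> float:
    """1 - SSres/SStot of the model's predictions against raw y.

    Returns 1.0 when y is constant and residuals vanish; may be negative
    for a model worse than the mean (clipped at 0 is NOT applied — a
    negative value is informative when comparing families).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - predict(model, x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-24 else 0.0
    return 1.0 - ss_res / ss_tot


_FITTERS = {
    "linear": fit_linear,
    "quadratic": fit_quadratic,
    "exponential": fit_exponential,
}


def select_family(
    x: Sequence[float],
    y: Sequence[float],
    candidates: Sequence[str] = ("linear", "quadratic", "exponential"),
) -> TrendModel:
    """Fit every admissible candidate family and keep the best.

    Families are compared by r2 on the ORIGINAL y scale (so the
    exponential's log-scale fit does not get an unfair scale advantage);
    near-ties (within 1e-12) go to the family with fewer coefficients.
    The exponential family is excluded automatically when any y <= 0.
    """
    if not candidates:
        raise ValueError("no candidate families given")
    unknown = set(candidates) - set(_FITTERS)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")
    y_arr = np.asarray(list(y), dtype=float)
    fitted: list[TrendModel] = []
    for fam in dict.fromkeys(candidates):  # preserve order, drop dups
        if fam == "exponential" and np.any(y_arr <= 0):
            continue
        try:
            fitted.append(_FITTERS[fam](x, y))
        except ValueError:
            continue
    if not fitted:
        raise ValueError("no admissible family could be fitted")
    # highest original-scale r2; ties -> fewest coefficients
    def sort_key(m: TrendModel):
        return (round(m.r2_original / 1e-12) * 1e-12, -m.n_params)

    return max(fitted, key=sort_key)


def invert_standard_curve(absorbance: float, curve: StandardCurve) -> float:
    """Concentration (mg/dL) from an absorbance reading via a linear standard curve."""
    return (absorbance - curve.intercept) / curve.slope
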