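"""Linearity diagnostics of a PWM brightness series (analysis method 1).

Three checks on a series of gradient-image profiles taken at PWM duty levels
(100, 80, 60, 40, 20):

* **Reflectance constancy** — the profile fit at level w should equal the
  reference (PWM-100) fit scaled by the constant w/100; the deviation curve
  quantifies departures from proportionality.
* **Slope vs PWM** — the first-order slope of each profile should be
  proportional to the duty level for a radiometrically linear camera; the R²
  of slope regressed on PWM is the summary.
* **Order selection** — residual-variance errors for polynomial orders
  1..max_order; the recommended order is the smallest one past which no level
  improves by more than a plateau tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import stats

from .profiles import IntensityProfile, PolynomialFit, fit_polynomial

__all__ = [
    "PWMSeries",
    "ConstancyResult",
    "SlopeResult",
    "OrderSelectionResult",
    "Method1Report",
    "reflectance_constancy",
    "slope_vs_pwm",
    "order_selection",
    "method1_report",
    "series_from_images",
]

REFERENCE_LEVEL = 100.0


@dataclass(frozen=True)
class PWMSeries:
    """Profiles of one camera indexed by PWM duty level.

    All profiles must share the same ``t`` grid and the reference level 100
    must be present.
    """

    profiles: Mapping[float, IntensityProfile]
    camera: str = ""

    def __post_init__(self) -> None:
        profiles = {float(k): v for k, v in self.profiles.items()}
        object.__setattr__(self, "profiles", profiles)
        if REFERENCE_LEVEL not in profiles:
            raise ValueError("series must contain the reference level 100")
        ref_t = profiles[REFERENCE_LEVEL].t
        for level, prof in profiles.items():
            if not np.array_equal(prof.t, ref_t):
                raise ValueError(f"profile at pwm={level} is on a different t grid")

    @property
    def levels(self) -> list[float]:
        """Levels in descending order (reference first)."""
        return sorted(self.profiles, reverse=True)

    @property
    def reference(self) -> IntensityProfile:
        return self.profiles[REFERENCE_LEVEL]

    def __len__(self) -> int:
        return len(self.profiles)


def series_from_images(
    images: Mapping[float, np.ndarray], *, camera: str = "", **extract_kwargs
) -> PWMSeries:
    """Build a :class:`PWMSeries` by extracting a profile from each image."""
    from .profiles import extract_profile

    profiles = {
        float(level): extract_profile(img, pwm=float(level), camera=camera, **extract_kwargs)
        for level, img in images.items()
    }
    return PWMSeries(profiles=profiles, camera=camera)


@dataclass(frozen=True)
class ConstancyResult:
    """Per-level deviation of the profile fit from the scaled reference fit."""

    levels: list[float]
    max_abs_deviation: dict[float, float]
    variance_deviation: dict[float, float]
    fit_grid: np.ndarray  # 100 evaluation points for the fitted curves
    baseline_grid: np.ndarray  # 10 evaluation points for the scaled baseline
    fit_curves: dict[float, np.ndarray]
    baseline_curves: dict[float, np.ndarray]


@dataclass(frozen=True)
class SlopeResult:
    """First-order slopes per level and their linearity versus PWM."""

    slopes: dict[float, float]
    slope_r2: float | None  # None when degenerate (all slopes equal)
    regression_slope: float | None
    regression_intercept: float | None

    @property
    def degenerate(self) -> bool:
        return self.slope_r2 is None


@dataclass(frozen=True)
class OrderSelectionResult:
    """Residual-variance errors per (level, order) and the recommended order."""

    orders: list[int]
    errors: dict[float, np.ndarray]  # level -> e[n] for n in orders
    recommended_order: int
    plateau_tolerance: float


@dataclass(frozen=True)
class Method1Report:
    constancy: ConstancyResult
    slopes: SlopeResult
    order_selection: OrderSelectionResult
    camera: str = ""


def reflectance_constancy(series: PWMSeries, order: int = 3) -> ConstancyResult:
    """Compare each level's fit against the reference fit scaled by w/100.

    For each non-reference level w, the profile is fitted at ``order`` and
    evaluated on a 100-point grid; the baseline — the reference fit scaled by
    the nominal constant w/100 — is evaluated on a 10-point grid.  The
    deviation summary is computed on the baseline grid, where both curves are
    defined, as the max-abs (and variance) of their difference.

    Raises
    ------
    ValueError
        If a level exceeds 100 (its nominal constant would be undefined).
    """
    for level in series.levels:
        if level > REFERENCE_LEVEL:
            raise ValueError(f"level {level} exceeds the reference level 100")

    ref_fit = fit_polynomial(series.reference, order)
    fit_grid = np.linspace(0.0, 1.0, 100)
    baseline_grid = np.linspace(0.0, 1.0, 10)
    ref_on_baseline = npoly.polyval(baseline_grid, ref_fit.coeffs)

    levels = [l for l in series.levels if l != REFERENCE_LEVEL]
    max_dev: dict[float, float] = {}
    var_dev: dict[float, float] = {}
    fit_curves: dict[float, np.ndarray] = {
        REFERENCE_LEVEL: npoly.polyval(fit_grid, ref_fit.coeffs)
    }
    baseline_curves: dict[float, np.ndarray] = {}
    for level in levels:
        fit_w = fit_polynomial(series.profiles[level], order)
        nominal = level / 100.0
        fit_curves[level] = npoly.polyval(fit_grid, fit_w.coeffs)
        baseline_curves[level] = nominal * ref_on_baseline
        diff = npoly.polyval(baseline_grid, fit_w.coeffs) - baseline_curves[level]
        max_dev[level] = float(np.max(np.abs(diff)))
        var_dev[level] = float(np.var(diff))

    return ConstancyResult(
        levels=levels,
        max_abs_deviation=max_dev,
        variance_deviation=var_dev,
        fit_grid=fit_grid,
        baseline_grid=baseline_grid,
        fit_curves=fit_curves,
        baseline_curves=baseline_curves,
    )


def slope_vs_pwm(series: PWMSeries) -> SlopeResult:
    """First-order slope per level and the R² of slope regressed on PWM.

    A linear camera under PWM-proportional lighting has slope proportional to
    the duty level, so the regression R² approaches 1.  If all slopes are
    identical the R² is undefined and reported as ``None`` (degenerate).
    """
    if len(series) < 2:
        raise ValueError("slope analysis requires at least 2 levels")
    slopes = {
        level: fit_polynomial(series.profiles[level], 1).slope for level in series.levels
    }
    pwm = np.array(sorted(slopes))
    s = np.array([slopes[p] for p in pwm])
    if np.ptp(s) == 0.0:
        return SlopeResult(slopes=slopes, slope_r2=None, regression_slope=None,
                           regression_intercept=None)
    res = stats.linregress(pwm, s)
    return SlopeResult(
        slopes=slopes,
        slope_r2=float(res.rvalue**2),
        regression_slope=float(res.slope),
        regression_intercept=float(res.intercept),
    )


def order_selection(
    series: PWMSeries,
    max_order: int = 6,
    *,
    plateau_tolerance: float = 0.05,
    atol: float = 1e-9,
) -> OrderSelectionResult:
    """Residual-variance errors for orders 1..max_order and a recommended order.

    The recommended order is the smallest ``n`` such that for *every* level
    the relative improvement ``(e[n] - e[n+1]) / e[n]`` falls below
    ``plateau_tolerance`` (an error already at or below ``atol`` counts as
    plateaued — relative changes of float-epsilon–sized errors are noise).
    Returns ``max_order`` if no plateau is found.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    npoints = len(series.reference)
    if max_order >= npoints:
        raise ValueError(f"max_order {max_order} >= number of points {npoints}")

    orders = list(range(1, max_order + 1))
    errors: dict[float, np.ndarray] = {}
    for level in series.levels:
        errors[level] = np.array(
            [fit_polynomial(series.profiles[level], n).error for n in orders]
        )

    recommended = max_order
    for i, n in enumerate(orders[:-1]):
        plateaued = True
        for e in errors.values():
            if e[i] <= atol:
                continue
            if (e[i] - e[i + 1]) / e[i] >= plateau_tolerance:
                plateaued = False
                break
        if plateaued:
            recommended = n
            break

    return OrderSelectionResult(
        orders=orders,
        errors=errors,
        recommended_order=recommended,
        plateau_tolerance=plateau_tolerance,
    )


def method1_report(
    series: PWMSeries, *, order: int = 3, max_order: int = 6
) -> Method1Report:
    """Run all three method-1 diagnostics on a series."""
    return Method1Report(
        constancy=reflectance_constancy(series, order),
        slopes=slope_vs_pwm(series),
        order_selection=order_selection(series, max_order),
        camera=series.camera,
    )
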