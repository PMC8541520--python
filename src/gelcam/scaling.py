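"""Optimal scaling constants and the linearity score (analysis method 2).

The reference (PWM-100) profile is fitted with a cubic polynomial ``p100``.
For every darker level w, the scalar ``d_w`` minimizing

    e_w(d) = var(y_w - d * yhat_100(t))

is found in closed form: the objective is quadratic in ``d``, so

    d_w = cov(y_w, yhat_100) / var(yhat_100),
    e_w(d_w) = var(y_w) * (1 - rho^2),

with ``rho`` the correlation of ``y_w`` and ``yhat_100`` (scaling the fitted
curve is identical to scaling the coefficients, since polynomial evaluation is
linear in the coefficients).  For a perfectly linear camera under
PWM-proportional lighting, ``d_w = w/100`` exactly; the root-mean-square
deviation of the recovered constants from that baseline is the camera's
linearity score — lower is more linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linearity import PWMSeries, REFERENCE_LEVEL
from .profiles import IntensityProfile, PolynomialFit, fit_polynomial

__all__ = [
    "ScalingResult",
    "fit_reference",
    "optimal_scaling_constant",
    "scaling_analysis",
    "rank_cameras",
]

#: Constants outside this range are physically implausible for a PWM series
#: (duty <= 100% of the reference) and are flagged, never clipped.
PLAUSIBLE_D_RANGE = (0.0, 1.5)


@dataclass(frozen=True)
class ScalingResult:
    """Per-level optimal constants and the camera's linearity score.

    Attributes
    ----------
    reference_fit : PolynomialFit
        Cubic fit of the PWM-100 profile.
    d : dict
        Level -> optimal scaling constant (``d[100] == 1`` by construction).
    errors : dict
        Level -> residual variance at the optimal constant.
    baseline : dict
        Level -> nominal constant w/100.
    linearity_rmse : float
        RMS of ``d_w - w/100`` over non-reference levels; the scalar camera
        score (0 for a perfectly linear camera).
    suspicious_levels : list
        Levels whose constant fell outside the plausible [0, 1.5] range.
    """

    reference_fit: PolynomialFit
    d: dict[float, float]
    errors: dict[float, float]
    baseline: dict[float, float]
    linearity_rmse: float
    suspicious_levels: list[float]
    camera: str = ""


def fit_reference(profile_100: IntensityProfile, order: int = 3) -> PolynomialFit:
    """Fit the reference (brightest, PWM-100) profile.

    Order 3 is the default everywhere: order selection on gradient series
    shows the error stops improving beyond the cubic.  Delegates to
    :func:`gelcam.profiles.fit_polynomial`.
    """
    return fit_polynomial(profile_100, order)


def optimal_scaling_constant(
    profile_w: IntensityProfile, reference_fit: PolynomialFit
) -> tuple[float, float]:
    """Closed-form constant minimizing ``var(y_w - d * yhat_100)``.

    Returns ``(d_w, e_w)`` where ``e_w`` is the residual variance at the
    optimum.

    Raises
    ------
    ValueError
        If the profiles are on different grids or the reference fit is flat
        (``var(yhat_100) == 0`` leaves ``d`` undetermined).
    """
    if not np.array_equal(profile_w.t, reference_fit.t):
        raise ValueError("profile and reference fit are on different t grids")
    yhat = reference_fit.fitted
    var_ref = float(np.var(yhat))
    # "flat" up to float jitter of the fit: variance negligible vs magnitude
    if var_ref <= np.finfo(float).eps * max(1.0, float(np.mean(yhat**2))):
        raise ValueError("reference profile has no spatial variation")
    y = profile_w.y
    cov = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
    d = cov / var_ref
    e = float(np.var(y - d * yhat))
    return d, e


def scaling_analysis(series: PWMSeries, *, order: int = 3) -> ScalingResult:
    """Recover scaling constants for every level and score the camera.

    The reference level gets ``d = 1`` by construction; each other level's
    constant comes from :func:`optimal_scaling_constant`.  The linearity RMSE
    aggregates the deviations from the ``w/100`` baseline over non-reference
    levels.
    """
    ref_fit = fit_reference(series.reference, order)
    d: dict[float, float] = {REFERENCE_LEVEL: 1.0}
    errors: dict[float, float] = {REFERENCE_LEVEL: ref_fit.error}
    baseline: dict[float, float] = {REFERENCE_LEVEL: 1.0}
    deviations = []
    suspicious: list[float] = []
    for level in series.levels:
        if level == REFERENCE_LEVEL:
            continue
        d_w, e_w = optimal_scaling_constant(series.profiles[level], ref_fit)
        d[level] = d_w
        errors[level] = e_w
        baseline[level] = level / 100.0
        deviations.append(d_w - level / 100.0)
        if not PLAUSIBLE_D_RANGE[0] <= d_w <= PLAUSIBLE_D_RANGE[1]:
            suspicious.append(level)
    rmse = float(np.sqrt(np.mean(np.square(deviations)))) if deviations else 0.0
    return ScalingResult(
        reference_fit=ref_fit,
        d=d,
        errors=errors,
        baseline=baseline,
        linearity_rmse=rmse,
        suspicious_levels=suspicious,
        camera=series.camera,
    )


def rank_cameras(results: dict[str, ScalingResult]) -> list[str]:
    """Camera names ordered best (lowest linearity RMSE) to worst."""
    return sorted(results, key=lambda name: results[name].linearity_rmse)
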