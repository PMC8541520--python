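"""Intensity profiles and polynomial fitting.

An image of a brightness gradient is reduced to a 1-D intensity profile
``y(t)`` on normalized positions ``t in [0, 1]`` (``t_i = i / (N - 1)``), and
the profile is summarized by an ordinary-least-squares polynomial fit.  The
fit quality metric used throughout the package is the *population variance of
the residuals*,

    e = var(y - yhat),   divisor N,

which by construction ignores any constant residual offset — a deliberate
property of the metric, documented where it matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

__all__ = [
    "IntensityProfile",
    "PolynomialFit",
    "extract_profile",
    "fit_polynomial",
    "evaluate_fit",
    "residual_error",
    "SaturationWarning",
]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


class SaturationWarning(UserWarning):
    """More than 1% of the pixels contributing to a profile are saturated."""


@dataclass(frozen=True)
class IntensityProfile:
    """A 1-D brightness trace at normalized positions.

    Attributes
    ----------
    t : numpy.ndarray
        Strictly increasing positions with ``t[0] == 0`` and ``t[-1] == 1``.
    y : numpy.ndarray
        Brightness in counts, same length as ``t``.
    pwm : float or None
        PWM duty level of the shot, if known.
    camera : str
        Camera identifier for report provenance.
    shot : int
        Shot index for report provenance.
    """

    t: np.ndarray
    y: np.ndarray
    pwm: float | None = None
    camera: str = ""
    shot: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or y.shape != t.shape or t.size < 2:
            raise ValueError("t and y must be equal-length 1-D arrays of length >= 2")
        if not (t[0] == 0.0 and t[-1] == 1.0 and np.all(np.diff(t) > 0)):
            raise ValueError("t must increase strictly from 0 to 1")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class PolynomialFit:
    """An order-``n`` OLS polynomial fit of a profile.

    ``coeffs`` are lowest-order first (``coeffs[k]`` multiplies ``t**k``).
    ``error`` is the population variance of the residuals on the fit grid.
    """

    order: int
    coeffs: np.ndarray
    t: np.ndarray
    fitted: np.ndarray
    error: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "fitted", np.asarray(self.fitted, dtype=float))
        if self.coeffs.size != self.order + 1:
            raise ValueError("coeffs length must equal order + 1")

    @property
    def slope(self) -> float:
        """First-order coefficient (the profile's linear slope)."""
        return float(self.coeffs[1]) if self.order >= 1 else 0.0

    def coeffs_highest_first(self) -> np.ndarray:
        """Coefficients in highest-order-first convention (numpy.polyval)."""
        return self.coeffs[::-1].copy()


def coeffs_from_highest_first(coeffs: np.ndarray) -> np.ndarray:
    """Convert highest-order-first coefficients to the internal convention."""
    return np.asarray(coeffs, dtype=float)[::-1].copy()


def extract_profile(
    image: np.ndarray,
    *,
    axis: str = "columns",
    channel: str | None = None,
    pwm: float | None = None,
    camera: str = "",
    shot: int = 0,
    saturation: float | None = None,
) -> IntensityProfile:
    """Reduce an image to an intensity profile along the gradient axis.

    The profile value at each position along the gradient axis is the
    arithmetic mean of all pixels at that position (averaging across the
    perpendicular axis suppresses noise); positions are normalized to
    ``t_i = i / (N - 1)``.

    Parameters
    ----------
    image
        2-D grayscale or 3-D RGB array.
    axis
        ``"columns"`` if the gradient runs along columns (profile indexed by
        column, averaged over rows; the simulator's convention) or ``"rows"``
        for the transpose.
    channel
        Required for RGB input (``"red"``/``"green"``/``"blue"`` or 0-2);
        must be omitted for grayscale input.
    saturation
        If given, a :class:`SaturationWarning` is emitted when more than 1%
        of the contributing pixels equal this value.  Saturated pixels are
        *not* excluded from the mean.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("image is empty")
    if img.ndim == 3:
        if channel is None:
            raise ValueError("RGB input requires a channel selection")
        idx = _CHANNELS[channel] if isinstance(channel, str) else int(channel)
        img = img[:, :, idx]
    elif img.ndim == 2:
        if channel is not None:
            raise ValueError("channel selection is invalid for grayscale input")
    else:
        raise ValueError(f"expected 2-D or 3-D image, got ndim={img.ndim}")

    if axis == "rows":
        img = img.T
    elif axis != "columns":
        raise ValueError(f"axis must be 'columns' or 'rows', got {axis!r}")
    if img.shape[1] < 2:
        raise ValueError("gradient axis must have at least 2 positions")

    if saturation is not None:
        frac = np.mean(img >= saturation)
        if frac > 0.01:
            warnings.warn(
                f"{frac:.1%} of contributing pixels are saturated", SaturationWarning
            )

    y = img.mean(axis=0, dtype=float)
    t = np.arange(y.size, dtype=float) / (y.size - 1)
    return IntensityProfile(t=t, y=y, pwm=pwm, camera=camera, shot=shot)


def fit_polynomial(profile: IntensityProfile, order: int) -> PolynomialFit:
    """OLS polynomial fit of a profile on the monomial basis of ``t``.

    Raises
    ------
    ValueError
        If ``order < 1`` or the fit is underdetermined
        (``order >= len(profile)``).
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if order >= len(profile):
        raise ValueError(
            f"order {order} requires more than {len(profile)} points (underdetermined)"
        )
    coeffs = npoly.polyfit(profile.t, profile.y, order)
    fitted = npoly.polyval(profile.t, coeffs)
    error = float(np.var(profile.y - fitted))
    return PolynomialFit(order=order, coeffs=coeffs, t=profile.t, fitted=fitted, error=error)


def evaluate_fit(fit: PolynomialFit, t_query: np.ndarray) -> np.ndarray:
    """Evaluate the fitted polynomial at ``t_query``.

    Queries outside ``[0, 1]`` are permitted (polynomials extrapolate) but
    trigger a warning, since the fit is only supported on the profile domain.
    """
    tq = np.asarray(t_query, dtype=float)
    if tq.size and (tq.min() < 0.0 or tq.max() > 1.0):
        warnings.warn("evaluating fit outside [0, 1] extrapolates", UserWarning)
    return npoly.polyval(tq, fit.coeffs)


def residual_error(profile: IntensityProfile, fit: PolynomialFit) -> float:
    """Population variance of ``y - yhat`` on the profile's grid.

    Note the blind spot: a residual that is a nonzero *constant* has zero
    variance, so this metric discounts uniform offsets entirely.
    """
    if len(profile) != fit.t.size or not np.array_equal(profile.t, fit.t):
        raise ValueError("profile and fit are on different t grids")
    return float(np.var(profile.y - fit.fitted))
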