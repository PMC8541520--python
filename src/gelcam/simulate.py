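"""Synthetic camera and gel-image simulator.

Generates seeded test images with known ground truth for the two evaluation
stages of the package:

* **Gradient test-sheet images** — a uniformly reflective sheet lit by an LED
  whose radiance is proportional to a PWM duty level, photographed by a camera
  with a parameterized radiometric response (gain, gamma, offset, clipping,
  additive Gaussian read noise).  The illumination has a smooth spatial profile
  along one axis, so each image is a brightness gradient.
* **Gel photographs** — agarose-gel images with one Gaussian band per lane
  whose integrated intensity is proportional to the lane's relative sample
  concentration, on a constant background, optionally warped projectively to
  emulate off-axis camera geometry.

Images are returned as float64 arrays clipped to ``[0, saturation]``;
quantization to integer bit depths happens only when images are written to
disk (see :mod:`gelcam.io`).  All randomness is driven by explicit seeds and
identical parameters + seed produce bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from skimage.transform import ProjectiveTransform, warp

__all__ = [
    "CameraResponseModel",
    "IlluminationField",
    "GelSceneSpec",
    "generate_gradient_image",
    "generate_pwm_series",
    "generate_gel_image",
    "default_rois",
    "DEFAULT_PWM_LEVELS",
    "DEFAULT_CONCENTRATIONS",
    "DEFAULT_SPATIAL_COEFFS",
]

#: PWM duty levels used throughout, brightest (reference) first.
DEFAULT_PWM_LEVELS: tuple[int, ...] = (100, 80, 60, 40, 20)

#: Relative concentrations of the dilution series loaded into the gel lanes.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (1.0, 1 / 2, 1 / 5, 1 / 10, 1 / 20)

#: Default spatial radiance profile: a monotone cubic over normalized position
#: t in [0,1], relative radiance 0.35 at t=0 rising to 1.0 at t=1.  Real LED
#: lighting is smooth but non-uniform; a cubic exercises polynomial order
#: selection realistically.
DEFAULT_SPATIAL_COEFFS: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)


@dataclass(frozen=True)
class CameraResponseModel:
    """Radiometric response of a synthetic camera.

    Pixel counts are ``clip(gain * L**gamma + offset + noise, 0, saturation)``
    where ``L`` is relative scene radiance.  ``gamma == 1`` is an ideally
    linear sensor — the property the evaluation methods score.

    Parameters
    ----------
    gain : float
        Counts per unit relative radiance; must be > 0.
    gamma : float
        Response exponent; must be > 0.  Values away from 1 distort linearity.
    offset : float
        Constant black-level offset in counts.
    saturation : float
        Full-well count (255 for 8-bit, 65535 for 16-bit); must be > 0.
    noise_sigma : float
        Standard deviation of additive Gaussian read noise in counts; >= 0.
    seed : int
        Base seed for the camera's noise stream.
    name : str
        Identifier used in reports and filenames.
    """

    gain: float = 230.0
    gamma: float = 1.0
    offset: float = 0.0
    saturation: float = 255.0
    noise_sigma: float = 2.0
    seed: int = 0
    name: str = "camera"

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.saturation <= 0:
            raise ValueError(f"saturation must be > 0, got {self.saturation}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


@dataclass(frozen=True)
class IlluminationField:
    """LED illumination: PWM-proportional radiance with a spatial profile.

    Radiance at normalized position ``t`` is
    ``(pwm / 100) * polyval(spatial_coeffs, t)`` — the LED is assumed exactly
    proportional to duty cycle, so any nonlinearity in the recorded series is
    attributable to the camera.
    """

    spatial_coeffs: tuple[float, ...] = DEFAULT_SPATIAL_COEFFS
    pwm: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.pwm <= 100:
            raise ValueError(f"pwm must be in [0, 100], got {self.pwm}")
        t = np.linspace(0.0, 1.0, 257)
        if np.any(npoly.polyval(t, self.spatial_coeffs) < 0):
            raise ValueError("spatial profile must be non-negative on [0, 1]")

    def radiance(self, t: np.ndarray) -> np.ndarray:
        """Relative radiance at normalized positions ``t``."""
        return (self.pwm / 100.0) * npoly.polyval(np.asarray(t, float), self.spatial_coeffs)

    def at_pwm(self, pwm: float) -> "IlluminationField":
        return IlluminationField(spatial_coeffs=self.spatial_coeffs, pwm=pwm)


def _level_seed(base_seed: int, level: float) -> np.random.SeedSequence:
    # Deterministic per-level stream: SeedSequence hashes its entropy pool, so
    # every (base_seed, level) pair gets an independent, reproducible stream.
    return np.random.SeedSequence([int(base_seed), int(round(level * 1000))])


def generate_gradient_image(
    camera: CameraResponseModel,
    fld: IlluminationField,
    shape: tuple[int, int] = (64, 256),
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one gradient test-sheet image.

    The image varies only along columns (rows are noise replicates): column
    ``c`` sees radiance ``L(t_c)`` with ``t_c = c / (cols - 1)`` and records
    ``clip(gain * L**gamma + offset + eps, 0, saturation)``.

    Parameters
    ----------
    camera, fld
        Response model and illumination.
    shape
        ``(rows, cols)``; both must be positive and cols >= 2.
    rng
        Optional generator for the noise stream; defaults to one seeded from
        ``camera.seed`` and ``fld.pwm``.

    Returns
    -------
    numpy.ndarray
        float64 image of the requested shape, clipped to [0, saturation].
    """
    rows, cols = shape
    if rows <= 0 or cols <= 1:
        raise ValueError(f"shape must have rows >= 1 and cols >= 2, got {shape}")
    if rng is None:
        rng = np.random.default_rng(_level_seed(camera.seed, fld.pwm))
    t = np.arange(cols, dtype=float) / (cols - 1)
    signal = camera.gain * fld.radiance(t) ** camera.gamma + camera.offset
    img = np.broadcast_to(signal, (rows, cols)).copy()
    if camera.noise_sigma > 0:
        img += rng.normal(0.0, camera.noise_sigma, size=(rows, cols))
    return np.clip(img, 0.0, camera.saturation)


def generate_pwm_series(
    camera: CameraResponseModel,
    fld: IlluminationField,
    pwm_levels: Sequence[float] = DEFAULT_PWM_LEVELS,
    shape: tuple[int, int] = (64, 256),
) -> dict[float, np.ndarray]:
    """Render one image per PWM level, sharing camera and field parameters.

    The reference level 100 must be present.  Per-level noise streams are
    derived deterministically from ``camera.seed`` so the series is
    reproducible level by level.
    """
    levels = [float(l) for l in pwm_levels]
    if len(set(levels)) != len(levels):
        raise ValueError("pwm levels must be distinct")
    if 100.0 not in levels:
        raise ValueError("pwm series must include the reference level 100")
    out: dict[float, np.ndarray] = {}
    for level in levels:
        if not 0 <= level <= 100:
            raise ValueError(f"pwm level out of range: {level}")
        out[level] = generate_gradient_image(camera, fld.at_pwm(level), shape)
    return out


@dataclass(frozen=True)
class GelSceneSpec:
    """Specification of a synthetic agarose-gel photograph.

    One lane per concentration; each lane carries a 2-D Gaussian band of peak
    amplitude ``band_peak * concentration`` centred on ``band_row``, on a
    constant ``background_level``.  The analytic band volume (background and
    noise excluded) is ``2*pi * peak * sigma_rows * sigma_cols``, exactly
    proportional to concentration by construction.
    """

    shape: tuple[int, int] = (200, 400)
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    band_row: int = 100
    band_sigma_rows: float = 6.0
    band_sigma_cols: float = 10.0
    band_peak: float = 180.0
    background_level: float = 30.0
    noise_sigma: float = 2.0
    saturation: float = 255.0
    perspective_corners: tuple[tuple[float, float], ...] | None = None
    seed: int = 0
    lane_margin: float = 4.0  # lane half-width must exceed this many sigmas

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if self.perspective_corners is not None and len(self.perspective_corners) != 4:
            raise ValueError("perspective_corners must have exactly 4 points")

    @property
    def lanes(self) -> int:
        return len(self.concentrations)

    def lane_centers(self) -> np.ndarray:
        """Column centres of the lanes, evenly spaced across the image."""
        cols = self.shape[1]
        return (np.arange(self.lanes) + 0.5) * cols / self.lanes


def default_rois(spec: GelSceneSpec, *, margin_sigmas: float = 3.5) -> list:
    """Generous band ROIs derived from the scene geometry (one per lane).

    Each ROI spans ``margin_sigmas`` standard deviations around the band
    centre, clipped to the lane; useful when quantifying images generated by
    :func:`generate_gel_image` without hand annotation.
    """
    from .gel import BandROI

    rois = []
    for lane, (center, conc) in enumerate(zip(spec.lane_centers(), spec.concentrations)):
        dr = margin_sigmas * spec.band_sigma_rows
        dc = margin_sigmas * spec.band_sigma_cols
        rois.append(
            BandROI(
                lane=lane,
                row0=int(round(spec.band_row - dr)),
                col0=int(round(center - dc)),
                row1=int(round(spec.band_row + dr)),
                col1=int(round(center + dc)),
                concentration=float(conc),
            )
        )
    return rois


def generate_gel_image(spec: GelSceneSpec) -> tuple[np.ndarray, list[float]]:
    """Render a gel image and return it with the analytic band volumes.

    Returns
    -------
    image : numpy.ndarray
        float64, clipped to [0, saturation].  If ``spec.perspective_corners``
        is set, a projective warp mapping the image corners onto those points
        is applied last (background fill outside the warped region).
    ground_truth_volumes : list of float
        ``2*pi * band_peak * c * sigma_rows * sigma_cols`` per lane —
        the analytic Gaussian integral, excluding background and noise.

    Raises
    ------
    ValueError
        If any band (out to ``lane_margin`` sigmas) would cross its lane
        boundary or the image edge.
    """
    rows, cols = spec.shape
    centers = spec.lane_centers()
    half_lane = cols / spec.lanes / 2.0
    if spec.band_sigma_cols * spec.lane_margin > half_lane:
        raise ValueError("band width exceeds lane boundaries")
    if (
        spec.band_row - spec.lane_margin * spec.band_sigma_rows < 0
        or spec.band_row + spec.lane_margin * spec.band_sigma_rows > rows
    ):
        raise ValueError("band does not fit inside image rows")

    r = np.arange(rows, dtype=float)[:, None]
    c = np.arange(cols, dtype=float)[None, :]
    img = np.full((rows, cols), float(spec.background_level))
    volumes: list[float] = []
    for center, conc in zip(centers, spec.concentrations):
        peak = spec.band_peak * conc
        img += peak * np.exp(
            -0.5 * ((r - spec.band_row) / spec.band_sigma_rows) ** 2
            - 0.5 * ((c - center) / spec.band_sigma_cols) ** 2
        )
        volumes.append(2.0 * np.pi * peak * spec.band_sigma_rows * spec.band_sigma_cols)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7]))
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, spec.saturation)

    if spec.perspective_corners is not None:
        from .gel import estimate_homography

        src = np.array(
            [[0, 0], [cols - 1, 0], [cols - 1, rows - 1], [0, rows - 1]], dtype=float
        )
        dst = np.asarray(spec.perspective_corners, dtype=float)
        tform = estimate_homography(src, dst)
        img = warp(
            img,
            tform.inverse,
            output_shape=(rows, cols),
            order=1,
            cval=float(spec.background_level),
            preserve_range=True,
        )
        img = np.clip(img, 0.0, spec.saturation)

    return img, volumes
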