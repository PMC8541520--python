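"""Gel-photograph quantification: rectification, densitometry, sensitivity.

The gel stage turns photographs of an electrophoresis gel carrying a dilution
series (relative concentrations 1, 1/2, 1/5, 1/10, 1/20) into a sensitivity
score per camera:

1. **Rectify** each photograph with a 4-point projective transform, so gels
   photographed by different cameras at different geometries land in a common
   pixel frame.
2. **Band volume** per lane: background-subtracted integrated intensity over
   a rectangular ROI, with the background estimated as the median of a border
   frame around the ROI and negative residuals clamped to zero — the standard
   densitometry convention, stated explicitly so results are reproducible.
3. **Dilution regression**: OLS of volume on concentration; the coefficient
   of determination R² measures linearity and the signal-to-noise ratio is
   its monotone transform SNR = R² / (1 - R²).
4. **Alternating-shot comparison**: each gel is photographed camera A, then
   camera B, then camera A again, so UV-induced fading affects both cameras
   symmetrically; shots are ranked by R² and the flanking-shot mean is
   compared with the centre shot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy import stats
from skimage.transform import ProjectiveTransform, warp

__all__ = [
    "estimate_homography",
    "CornerQuad",
    "BandROI",
    "DilutionSeriesResult",
    "ExperimentComparison",
    "ExperimentReport",
    "rectify",
    "band_volume",
    "dilution_regression",
    "snr_from_r2",
    "r2_from_snr",
    "rank_experiment",
    "compare_experiments",
    "find_bands",
]


def estimate_homography(src: np.ndarray, dst: np.ndarray) -> ProjectiveTransform:
    """Projective transform mapping ``src`` points onto ``dst`` points.

    Four point pairs determine the 3×3 homography up to scale (8 unknowns).

    Raises
    ------
    ValueError
        If the point configuration is degenerate.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(src, dst)
        if not tform:
            raise ValueError("could not estimate homography (degenerate points)")
        return tform
    tform = ProjectiveTransform()
    if not tform.estimate(src, dst):
        raise ValueError("could not estimate homography (degenerate points)")
    return tform


@dataclass(frozen=True)
class CornerQuad:
    """Four gel corners in pixel (x, y) coordinates plus the target size.

    Corner order is top-left, top-right, bottom-right, bottom-left.  The quad
    must be convex and non-degenerate.
    """

    corners: tuple[tuple[float, float], ...]
    target_width: int
    target_height: int

    def __post_init__(self) -> None:
        corners = tuple((float(x), float(y)) for x, y in self.corners)
        object.__setattr__(self, "corners", corners)
        if len(corners) != 4:
            raise ValueError("quad needs exactly 4 corners")
        if self.target_width < 1 or self.target_height < 1:
            raise ValueError("target size must be positive")
        pts = np.asarray(corners)
        # convexity: cross products of consecutive edges share a sign and
        # no three points are collinear
        crosses = []
        for i in range(4):
            a, b, c = pts[i], pts[(i + 1) % 4], pts[(i + 2) % 4]
            u, v = b - a, c - b
            crosses.append(u[0] * v[1] - u[1] * v[0])
        crosses = np.asarray(crosses)
        if np.any(crosses == 0) or not (np.all(crosses > 0) or np.all(crosses < 0)):
            raise ValueError("quad is degenerate or non-convex")

    def target_corners(self) -> np.ndarray:
        """Rectangle corners the quad maps onto, same order, (x, y)."""
        w, h = self.target_width - 1, self.target_height - 1
        return np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)


def rectify(image: np.ndarray, quad: CornerQuad, *, cval: float = 0.0) -> np.ndarray:
    """Map the quad region of ``image`` onto an upright target rectangle.

    The 3×3 homography (8 unknowns from 4 point pairs) is estimated between
    the quad corners and the target rectangle corners, and the image is
    resampled with bilinear interpolation.
    """
    img = np.asarray(image, dtype=float)
    # warp() wants the map from output coords to input coords, i.e.
    # rectangle -> quad.
    tform = estimate_homography(quad.target_corners(), np.asarray(quad.corners))
    return warp(
        img,
        tform,
        output_shape=(quad.target_height, quad.target_width),
        order=1,
        cval=cval,
        preserve_range=True,
    )


@dataclass(frozen=True)
class BandROI:
    """Rectangular region of interest around one band.

    Coordinates are 0-based, half-open: rows ``row0 <= r < row1``, columns
    ``col0 <= c < col1``.
    """

    lane: int
    row0: int
    col0: int
    row1: int
    col1: int
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError("ROI must satisfy row0 < row1 and col0 < col1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI coordinates must be non-negative")


def band_volume(
    image: np.ndarray,
    roi: BandROI,
    border_width: int = 3,
    *,
    background: float | None = None,
) -> float:
    """Background-subtracted integrated intensity of one band.

    The background is the *median* of the frame of ``border_width`` pixels
    surrounding the ROI (or the externally supplied ``background``); the
    volume is the sum over the ROI of ``max(pixel - background, 0)``.  Both
    the ROI and its border must lie inside the image.
    """
    if border_width < 1:
        raise ValueError("border_width must be >= 1")
    img = np.asarray(image, dtype=float)
    r0, c0, r1, c1 = roi.row0, roi.col0, roi.row1, roi.col1
    if r0 - border_width < 0 or c0 - border_width < 0:
        raise ValueError("ROI border extends past the image start")
    if r1 + border_width > img.shape[0] or c1 + border_width > img.shape[1]:
        raise ValueError("ROI border extends past the image end")
    if background is None:
        outer = img[
            r0 - border_width : r1 + border_width, c0 - border_width : c1 + border_width
        ]
        mask = np.ones(outer.shape, dtype=bool)
        mask[border_width:-border_width, border_width:-border_width] = False
        background = float(np.median(outer[mask]))
    inner = img[r0:r1, c0:c1]
    return float(np.sum(np.maximum(inner - float(background), 0.0)))


def snr_from_r2(r2: float) -> float:
    """Signal-to-noise ratio SNR = R² / (1 - R²); infinite at R² = 1."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must be in [0, 1], got {r2}")
    if r2 == 1.0:
        return math.inf
    return r2 / (1.0 - r2)


def r2_from_snr(snr: float) -> float:
    """Inverse transform R² = SNR / (1 + SNR)."""
    if snr < 0:
        raise ValueError(f"snr must be >= 0, got {snr}")
    if math.isinf(snr):
        return 1.0
    return snr / (1.0 + snr)


@dataclass(frozen=True)
class DilutionSeriesResult:
    """Regression of band volumes on relative concentrations.

    ``degenerate`` is set when R² is undefined (all volumes identical) or
    exactly 1 (SNR infinite).
    """

    volumes: tuple[float, ...]
    concentrations: tuple[float, ...]
    slope: float
    intercept: float
    r2: float | None
    snr: float | None
    degenerate: bool = False
    camera: str = ""
    shot: int = 0


def dilution_regression(
    volumes: Sequence[float],
    concentrations: Sequence[float],
    *,
    camera: str = "",
    shot: int = 0,
) -> DilutionSeriesResult:
    """OLS line ``volume = slope * concentration + intercept`` plus R² and SNR.

    Requires at least 3 points with distinct concentrations.  If all volumes
    are identical the R² is undefined and the result carries a degenerate
    flag; an exact fit (R² = 1) reports an infinite SNR, also flagged.
    """
    v = np.asarray(volumes, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if v.shape != c.shape or v.ndim != 1:
        raise ValueError("volumes and concentrations must be equal-length 1-D")
    if v.size < 3:
        raise ValueError("dilution regression needs at least 3 points")
    if np.unique(c).size != c.size:
        raise ValueError("concentrations must be distinct")
    if np.ptp(v) == 0.0:
        res = stats.linregress(c, v)
        return DilutionSeriesResult(
            volumes=tuple(v), concentrations=tuple(c),
            slope=float(res.slope), intercept=float(res.intercept),
            r2=None, snr=None, degenerate=True, camera=camera, shot=shot,
        )
    res = stats.linregress(c, v)
    r2 = float(res.rvalue**2)
    # an exact fit should report r2 = 1 / infinite snr, not float jitter
    if r2 >= 1.0 - 1e-12:
        r2 = 1.0
    snr = snr_from_r2(r2)
    return DilutionSeriesResult(
        volumes=tuple(v), concentrations=tuple(c),
        slope=float(res.slope), intercept=float(res.intercept),
        r2=r2, snr=snr, degenerate=math.isinf(snr),
        camera=camera, shot=shot,
    )


def rank_experiment(shot_r2: Sequence[float]) -> tuple[tuple[int, int, int], bool]:
    """Rank three shots by R² (1 = largest, 3 = smallest).

    Ties are broken by acquisition order — the earlier shot gets the better
    rank — and reported via the returned tie flag.
    """
    r2 = [float(x) for x in shot_r2]
    if len(r2) != 3:
        raise ValueError("rank_experiment expects exactly 3 R² values")
    if not all(math.isfinite(x) and 0.0 <= x <= 1.0 for x in r2):
        raise ValueError("R² values must be finite and in [0, 1]")
    # sort by (-r2, acquisition index): earlier shot wins ties
    order = sorted(range(3), key=lambda i: (-r2[i], i))
    ranks = [0, 0, 0]
    for rank, idx in enumerate(order, start=1):
        ranks[idx] = rank
    tie = len(set(r2)) < 3
    return (ranks[0], ranks[1], ranks[2]), tie


@dataclass(frozen=True)
class ExperimentComparison:
    """One alternating-shot experiment: camera A, camera B, camera A.

    ``shots`` are the three per-shot dilution-series results in acquisition
    order; shots 1 and 3 (the flanks) belong to ``camera_a`` and shot 2 (the
    centre) to ``camera_b``.  ``exposure_factors`` rescale each shot's slope
    before the cross-camera slope comparison (default: no rescaling).
    """

    name: str
    camera_a: str
    camera_b: str
    shots: tuple[DilutionSeriesResult, DilutionSeriesResult, DilutionSeriesResult]
    exposure_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.shots) != 3:
            raise ValueError("an experiment has exactly 3 shots (A, B, A)")
        cams = [s.camera for s in self.shots]
        if any(cams) and (cams[0] != cams[2] or cams[0] == cams[1]):
            raise ValueError(
                f"shot order must be A, B, A; got cameras {cams}"
            )


@dataclass(frozen=True)
class ExperimentReport:
    """Derived comparison quantities for one experiment."""

    name: str
    camera_a: str
    camera_b: str
    shot_r2: tuple[float, float, float]
    ranks: tuple[int, int, int]
    tie: bool
    flank_mean: float  # mean R² of shots 1 and 3 (camera A)
    center_r2: float  # R² of shot 2 (camera B)
    slope_ratio: float  # camera A mean normalized slope / camera B slope


def _effective_r2(shot: DilutionSeriesResult) -> float:
    if shot.r2 is None:
        raise ValueError("shot has undefined R² (degenerate constant volumes)")
    return shot.r2


def compare_experiments(
    experiments: Sequence[ExperimentComparison],
) -> tuple[list[ExperimentReport], dict[str, float]]:
    """Per-experiment flank-vs-centre comparison and per-camera R² summary.

    Returns the per-experiment reports and a mapping camera -> mean R² over
    all of that camera's shots across experiments.
    """
    reports: list[ExperimentReport] = []
    per_camera: dict[str, list[float]] = {}
    for exp in experiments:
        r2 = tuple(_effective_r2(s) for s in exp.shots)
        ranks, tie = rank_experiment(r2)
        norm_slopes = [
            s.slope / f for s, f in zip(exp.shots, exp.exposure_factors)
        ]
        center_slope = norm_slopes[1]
        flank_slope = 0.5 * (norm_slopes[0] + norm_slopes[2])
        slope_ratio = flank_slope / center_slope if center_slope != 0 else math.inf
        reports.append(
            ExperimentReport(
                name=exp.name,
                camera_a=exp.camera_a,
                camera_b=exp.camera_b,
                shot_r2=r2,
                ranks=ranks,
                tie=tie,
                flank_mean=0.5 * (r2[0] + r2[2]),
                center_r2=r2[1],
                slope_ratio=slope_ratio,
            )
        )
        per_camera.setdefault(exp.camera_a, []).extend([r2[0], r2[2]])
        per_camera.setdefault(exp.camera_b, []).append(r2[1])
    summary = {cam: float(np.mean(vals)) for cam, vals in per_camera.items()}
    return reports, summary


def find_bands(
    image: np.ndarray,
    *,
    band_row: int | None = None,
    row_halfwidth: int = 20,
    smooth_window: int = 5,
    min_prominence_frac: float = 0.05,
) -> list[int]:
    """Automatic band finder: peak columns of the smoothed column profile.

    Convenience helper for un-annotated gels; annotated ROIs remain the
    primary quantification path.  The column profile (mean over a row stripe
    around ``band_row``, or the whole image) is smoothed with a moving
    average of ``smooth_window`` pixels and peaks with prominence of at least
    ``min_prominence_frac`` of the profile's dynamic range are returned.
    """
    img = np.asarray(image, dtype=float)
    if band_row is not None:
        r0 = max(0, band_row - row_halfwidth)
        r1 = min(img.shape[0], band_row + row_halfwidth)
        img = img[r0:r1]
    profile = img.mean(axis=0)
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(profile, kernel, mode="same")
    prominence = min_prominence_frac * max(np.ptp(smooth), 1e-12)
    peaks, _ = sp_signal.find_peaks(smooth, prominence=prominence)
    return [int(p) for p in peaks]
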