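"""Gel quantification: rectification, densitometry, R²/SNR, rank comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from gelcam import (
    BandROI,
    CornerQuad,
    DilutionSeriesResult,
    ExperimentComparison,
    GelSceneSpec,
    band_volume,
    compare_experiments,
    default_rois,
    dilution_regression,
    find_bands,
    generate_gel_image,
    r2_from_snr,
    rank_experiment,
    rectify,
    snr_from_r2,
)
from gelcam.gel import estimate_homography

# Printed per-shot R² triplets and ranks of the four alternating-shot
# experiments (DSLR/AR0130 and AR0130/IMX179 comparisons).
PUBLISHED_EXPERIMENTS = [
    ((0.9962, 0.9866, 0.9947), (1, 3, 2)),
    ((0.9884, 0.9995, 0.9793), (2, 1, 3)),
    ((0.995, 0.9944, 0.9943), (1, 2, 3)),
    ((0.9561, 0.9952, 0.9942), (3, 1, 2)),
]


def dlt_homography(src, dst):
    """8x8 linear-system oracle for the 4-point homography (h33 = 1)."""
    A, b = [], []
    for (x, y), (u, v) in zip(src, dst):
        A.append([x, y, 1, 0, 0, 0, -u * x, -u * y])
        b.append(u)
        A.append([0, 0, 0, x, y, 1, -v * x, -v * y])
        b.append(v)
    h = np.linalg.solve(np.asarray(A, float), np.asarray(b, float))
    return np.append(h, 1.0).reshape(3, 3)


class TestRectify:
    def test_identity_quad_is_noop(self):
        rng = np.random.default_rng(41)
        img = rng.uniform(0, 255, (40, 60))
        quad = CornerQuad(
            corners=((0, 0), (59, 0), (59, 39), (0, 39)),
            target_width=60, target_height=40,
        )
        np.testing.assert_allclose(rectify(img, quad), img, atol=1e-6)

    def test_homography_matches_linear_system_oracle(self):
        src = [(0.0, 0.0), (99.0, 0.0), (99.0, 49.0), (0.0, 49.0)]
        dst = [(3.0, 5.0), (95.0, 2.0), (97.0, 47.0), (1.0, 44.0)]
        tform = estimate_homography(np.array(src), np.array(dst))
        H = tform.params / tform.params[2, 2]
        np.testing.assert_allclose(H, dlt_homography(src, dst), atol=1e-9)

    def test_warp_rectify_round_trip_small_error(self):
        spec = GelSceneSpec(noise_sigma=0.0)
        flat, _ = generate_gel_image(spec)
        corners = ((8.0, 5.0), (392.0, 7.0), (394.0, 193.0), (6.0, 191.0))
        warped, _ = generate_gel_image(
            GelSceneSpec(noise_sigma=0.0, perspective_corners=corners)
        )
        quad = CornerQuad(corners=corners, target_width=400, target_height=200)
        rect = rectify(warped, quad, cval=spec.background_level)
        interior = (slice(10, -10), slice(10, -10))
        mae = np.mean(np.abs(rect[interior] - flat[interior]))
        assert mae < 2.0

    def test_degenerate_quad_rejected(self):
        with pytest.raises(ValueError):
            CornerQuad(corners=((0, 0), (10, 0), (20, 0), (0, 10)),
                       target_width=10, target_height=10)


class TestBandVolume:
    def test_uniform_image_has_zero_volume(self):
        img = np.full((50, 50), 40.0)
        roi = BandROI(lane=0, row0=10, col0=10, row1=30, col1=30)
        assert band_volume(img, roi) == 0.0

    def test_gaussian_band_matches_analytic_integral(self):
        r = np.arange(80)[:, None]
        c = np.arange(80)[None, :]
        img = 100.0 * np.exp(-0.5 * ((r - 40) / 3.0) ** 2 - 0.5 * ((c - 40) / 3.0) ** 2)
        roi = BandROI(lane=0, row0=20, col0=20, row1=60, col1=60)
        assert band_volume(img, roi) == pytest.approx(2 * np.pi * 100 * 9, rel=0.01)

    def test_dilution_gel_volume_ratios_match_concentrations(self, gel_spec):
        img, _ = generate_gel_image(gel_spec)
        vols = [band_volume(img, roi) for roi in default_rois(gel_spec)]
        ratios = np.array(vols) / vols[0]
        np.testing.assert_allclose(ratios, gel_spec.concentrations, rtol=0.01)

    def test_additivity_over_roi_partition_with_fixed_background(self, gel_spec):
        img, _ = generate_gel_image(gel_spec)
        roi = default_rois(gel_spec)[0]
        mid = (roi.row0 + roi.row1) // 2
        top = BandROI(lane=0, row0=roi.row0, col0=roi.col0, row1=mid, col1=roi.col1)
        bot = BandROI(lane=0, row0=mid, col0=roi.col0, row1=roi.row1, col1=roi.col1)
        bg = gel_spec.background_level
        whole = band_volume(img, roi, background=bg)
        parts = band_volume(img, top, background=bg) + band_volume(img, bot, background=bg)
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_out_of_bounds_and_bad_border_rejected(self):
        img = np.zeros((20, 20))
        roi = BandROI(lane=0, row0=0, col0=5, row1=10, col1=15)
        with pytest.raises(ValueError):
            band_volume(img, roi)  # border extends past row 0
        inner = BandROI(lane=0, row0=5, col0=5, row1=10, col1=15)
        with pytest.raises(ValueError):
            band_volume(img, inner, border_width=0)


class TestDilutionRegression:
    def test_exact_proportional_volumes(self):
        concs = (1.0, 0.5, 0.2, 0.1, 0.05)
        res = dilution_regression([1000 * c for c in concs], concs)
        assert res.slope == pytest.approx(1000.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0)
        assert math.isinf(res.snr) and res.degenerate

    def test_matches_normal_equations_oracle(self):
        vols = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        concs = np.array([1.0, 0.5, 0.2, 0.1, 0.05])
        res = dilution_regression(vols, concs)
        X = np.column_stack([concs, np.ones(5)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ vols)
        fitted = slope * concs + intercept
        r2 = 1 - np.sum((vols - fitted) ** 2) / np.sum((vols - vols.mean()) ** 2)
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-12)
        assert res.r2 == pytest.approx(r2, rel=1e-10)

    def test_identical_volumes_flagged_degenerate(self):
        res = dilution_regression([7.0, 7.0, 7.0], [1.0, 0.5, 0.2])
        assert res.degenerate and res.r2 is None and res.snr is None

    def test_input_validation(self):
        with pytest.raises(ValueError):
            dilution_regression([1.0, 2.0], [1.0, 0.5])
        with pytest.raises(ValueError):
            dilution_regression([1.0, 2.0, 3.0], [1.0, 1.0, 0.5])


class TestSNR:
    def test_round_trip_identity_on_grid(self):
        for r2 in np.linspace(0.0, 0.999, 1000):
            assert r2_from_snr(snr_from_r2(r2)) == pytest.approx(r2, abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.linspace(0.0, 0.9999, 1000)
        snrs = [snr_from_r2(x) for x in grid]
        assert all(a < b for a, b in zip(snrs, snrs[1:]))

    def test_half_r2_gives_unit_snr(self):
        assert snr_from_r2(0.5) == pytest.approx(1.0)

    def test_boundaries(self):
        assert snr_from_r2(0.0) == 0.0
        assert math.isinf(snr_from_r2(1.0))
        assert r2_from_snr(math.inf) == 1.0
        with pytest.raises(ValueError):
            snr_from_r2(1.1)


class TestRankExperiment:
    @pytest.mark.parametrize("r2,expected", PUBLISHED_EXPERIMENTS)
    def test_published_triplets(self, r2, expected):
        ranks, tie = rank_experiment(r2)
        assert ranks == expected and not tie

    def test_tie_broken_by_acquisition_order(self):
        ranks, tie = rank_experiment((0.9, 0.9, 0.8))
        assert ranks == (1, 2, 3) and tie

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_experiment((0.9, float("nan"), 0.8))


def _shot(r2, slope=100.0, camera="", shot=0):
    snr = snr_from_r2(r2) if r2 < 1 else math.inf
    return DilutionSeriesResult(
        volumes=(3.0, 2.0, 1.0), concentrations=(1.0, 0.5, 0.2),
        slope=slope, intercept=0.0, r2=r2, snr=snr, camera=camera, shot=shot,
    )


class TestCompareExperiments:
    def test_identical_shots_give_equal_flank_and_center(self):
        exp = ExperimentComparison(
            name="e", camera_a="A", camera_b="B",
            shots=(_shot(0.99, camera="A"), _shot(0.99, camera="B"),
                   _shot(0.99, camera="A")),
        )
        reports, _ = compare_experiments([exp])
        assert reports[0].flank_mean == pytest.approx(reports[0].center_r2)
        assert reports[0].slope_ratio == pytest.approx(1.0)

    def test_published_experiment_flank_vs_center(self):
        r2 = PUBLISHED_EXPERIMENTS[0][0]
        exp = ExperimentComparison(
            name="exp1", camera_a="DSLR", camera_b="AR0130",
            shots=(_shot(r2[0], camera="DSLR"), _shot(r2[1], camera="AR0130"),
                   _shot(r2[2], camera="DSLR")),
        )
        reports, summary = compare_experiments([exp])
        rep = reports[0]
        assert rep.flank_mean == pytest.approx(0.5 * (0.9962 + 0.9947))
        assert rep.center_r2 == pytest.approx(0.9866)
        assert rep.center_r2 < rep.flank_mean
        assert rep.ranks == (1, 3, 2)
        assert summary["DSLR"] == pytest.approx(np.mean([0.9962, 0.9947]))

    def test_noisier_flank_camera_loses_to_center_camera(self):
        """Majority over 20 seeds: less noisy centre camera has higher R²."""
        wins = 0
        for seed in range(20):
            shots = []
            for shot_idx, noise in enumerate([6.0, 1.0, 6.0]):
                spec = GelSceneSpec(noise_sigma=noise, seed=1000 * seed + shot_idx)
                img, _ = generate_gel_image(spec)
                vols = [band_volume(img, r) for r in default_rois(spec)]
                shots.append(
                    dilution_regression(vols, spec.concentrations,
                                        camera="A" if shot_idx != 1 else "B",
                                        shot=shot_idx + 1)
                )
            exp = ExperimentComparison(
                name=f"s{seed}", camera_a="A", camera_b="B", shots=tuple(shots)
            )
            rep, _ = compare_experiments([exp])
            if rep[0].center_r2 > rep[0].flank_mean:
                wins += 1
        assert wins >= 14

    def test_malformed_shot_order_rejected(self):
        with pytest.raises(ValueError, match="A, B, A"):
            ExperimentComparison(
                name="bad", camera_a="A", camera_b="B",
                shots=(_shot(0.9, camera="A"), _shot(0.9, camera="B"),
                       _shot(0.9, camera="B")),
            )


class TestSensitivityRecovery:
    def test_noise_never_increases_median_r2(self):
        """Median dilution R² over seeds is non-increasing in simulator noise."""
        medians = []
        for noise in (0.5, 4.0, 12.0):
            r2s = []
            for seed in range(20):
                spec = GelSceneSpec(noise_sigma=noise, seed=seed, shape=(120, 300),
                                    band_sigma_rows=4.0, band_sigma_cols=7.0,
                                    band_row=60)
                img, _ = generate_gel_image(spec)
                vols = [band_volume(img, r) for r in default_rois(spec)]
                r2s.append(dilution_regression(vols, spec.concentrations).r2)
            medians.append(float(np.median(r2s)))
        assert medians[0] >= medians[1] >= medians[2]


class TestFindBands:
    def test_detects_all_lanes(self, gel_spec):
        img, _ = generate_gel_image(gel_spec)
        # 3% prominence: the faintest (1/20) band sits at the 5% default limit
        peaks = find_bands(img, band_row=gel_spec.band_row, min_prominence_frac=0.03)
        centers = gel_spec.lane_centers()
        assert len(peaks) == gel_spec.lanes
        for peak, center in zip(peaks, centers):
            assert abs(peak - center) <= 3
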