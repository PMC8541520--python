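"""Pipeline execution and report generation.

``run_pipeline`` executes the selected stages in dependency order
(simulate-gradient → method1 → method2 → simulate-gel → gel-quant → compare),
writes tidy CSV tables and a JSON summary to the output directory, and
optionally renders diagnostic plots.  Every table row carries provenance
(camera, PWM level, shot, seed) and identical config + seed produces
byte-identical CSV/JSON output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as gio
from .config import RunConfig
from .gel import (
    ExperimentComparison,
    compare_experiments,
    band_volume,
    dilution_regression,
)
from .linearity import PWMSeries, method1_report, series_from_images
from .profiles import extract_profile
from .scaling import ScalingResult, rank_cameras, scaling_analysis
from .simulate import (
    CameraResponseModel,
    GelSceneSpec,
    IlluminationField,
    default_rois,
    generate_gel_image,
    generate_pwm_series,
)

__all__ = ["run_pipeline", "demo_config"]


def _derived_seed(base: int, *salt: int) -> int:
    """Deterministic 31-bit sub-seed for an independent random stream."""
    ss = np.random.SeedSequence([int(base), *[int(s) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))


def _camera_models(config: RunConfig) -> list[CameraResponseModel]:
    return [
        CameraResponseModel(
            gain=c.gain,
            gamma=c.gamma,
            offset=c.offset,
            saturation=c.saturation,
            noise_sigma=c.noise_sigma,
            seed=_derived_seed(config.seed, i),
            name=c.name,
        )
        for i, c in enumerate(config.cameras)
    ]


def _load_gradient_series(config: RunConfig) -> dict[str, PWMSeries]:
    """Read gradient images from ``gradient_dir`` ({camera}_pwm{level}.png)."""
    root = Path(config.gradient_dir)
    names = sorted({p.stem.rsplit("_pwm", 1)[0] for p in root.glob("*_pwm*.png")})
    if not names:
        raise ValueError(f"no gradient images found in {root}")
    out = {}
    for name in names:
        images = {}
        for level in config.pwm_levels:
            path = root / f"{name}_pwm{int(level)}.png"
            if not path.exists():
                raise ValueError(f"missing gradient image: {path}")
            images[level] = gio.read_image(path)
        out[name] = series_from_images(images, camera=name)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write report artifacts.

    Returns the JSON-serializable summary that is also written to
    ``summary.json`` in the output directory.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    # config echo for provenance; the output path itself is where the file
    # lives, so leaving it out keeps reruns byte-comparable across directories
    config_echo = config.to_dict()
    config_echo.pop("output_dir", None)
    summary: dict[str, Any] = {"config": config_echo, "seed": config.seed}

    series_by_camera: dict[str, PWMSeries] = {}
    if "simulate-gradient" in config.stages:
        fld = IlluminationField(spatial_coeffs=config.spatial_coeffs)
        rows = []
        for cam in _camera_models(config):
            images = generate_pwm_series(cam, fld, config.pwm_levels, config.image_shape)
            if config.write_images:
                for level, img in images.items():
                    gio.write_image(
                        outdir / f"{cam.name}_pwm{int(level)}.png",
                        img,
                        bit_depth=config.bit_depth,
                    )
            series_by_camera[cam.name] = series_from_images(images, camera=cam.name)
            for level, prof in series_by_camera[cam.name].profiles.items():
                for t, y in zip(prof.t, prof.y):
                    rows.append(
                        {"camera": cam.name, "pwm": level, "seed": cam.seed, "t": t, "y": y}
                    )
        pd.DataFrame(rows).to_csv(outdir / "profiles.csv", index=False)
    elif {"method1", "method2"} & set(config.stages):
        series_by_camera = _load_gradient_series(config)

    if "method1" in config.stages:
        _run_method1(config, series_by_camera, outdir, summary)

    scaling_by_camera: dict[str, ScalingResult] = {}
    if "method2" in config.stages:
        scaling_by_camera = _run_method2(config, series_by_camera, outdir, summary)

    gel_results = None
    if "simulate-gel" in config.stages:
        gel_results = _run_gel_stage(
            config, scaling_by_camera, outdir, summary,
            quantify="gel-quant" in config.stages,
        )

    if "compare" in config.stages and gel_results is not None:
        _run_compare(gel_results, outdir, summary)

    if config.plots:
        _render_plots(config, series_by_camera, scaling_by_camera, outdir, summary)

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )
    return summary


def _run_method1(config, series_by_camera, outdir, summary) -> None:
    const_rows, slope_rows, order_rows = [], [], []
    m1_summary = {}
    for name, series in series_by_camera.items():
        report = method1_report(series, order=config.fit_order, max_order=config.max_order)
        for level in report.constancy.levels:
            const_rows.append(
                {
                    "camera": name,
                    "pwm": level,
                    "max_abs_deviation": report.constancy.max_abs_deviation[level],
                    "variance_deviation": report.constancy.variance_deviation[level],
                }
            )
        for level, slope in report.slopes.slopes.items():
            slope_rows.append({"camera": name, "pwm": level, "slope": slope})
        for level, errs in report.order_selection.errors.items():
            for n, e in zip(report.order_selection.orders, errs):
                order_rows.append({"camera": name, "pwm": level, "order": n, "error": e})
        m1_summary[name] = {
            "slope_r2": report.slopes.slope_r2,
            "recommended_order": report.order_selection.recommended_order,
        }
    pd.DataFrame(const_rows).to_csv(outdir / "method1_constancy.csv", index=False)
    pd.DataFrame(slope_rows).to_csv(outdir / "method1_slopes.csv", index=False)
    pd.DataFrame(order_rows).to_csv(outdir / "method1_order_errors.csv", index=False)
    summary["method1"] = m1_summary


def _run_method2(config, series_by_camera, outdir, summary) -> dict[str, ScalingResult]:
    results = {
        name: scaling_analysis(series, order=config.fit_order)
        for name, series in series_by_camera.items()
    }
    rows = []
    for name, res in results.items():
        for level in sorted(res.d, reverse=True):
            rows.append(
                {
                    "camera": name,
                    "pwm": level,
                    "d": res.d[level],
                    "baseline": res.baseline[level],
                    "error": res.errors[level],
                    "suspicious": level in res.suspicious_levels,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "method2_constants.csv", index=False)
    ranking = rank_cameras(results)
    summary["method2"] = {
        "linearity_rmse": {n: results[n].linearity_rmse for n in results},
        "ranking": ranking,
    }
    return results


def _run_gel_stage(config, scaling_by_camera, outdir, summary, *, quantify=True):
    """Alternating-shot gel experiments between the two most linear cameras."""
    g = config.gel
    if scaling_by_camera:
        order = rank_cameras(scaling_by_camera)
    else:
        order = [c.name for c in config.cameras]
    if len(order) < 2:
        raise ValueError("gel stage needs at least 2 cameras")
    cam_by_name = {c.name: c for c in config.cameras}
    cam_a, cam_b = order[0], order[1]

    experiments = []
    vol_rows, reg_rows = [], []
    for exp_idx, (first, second) in enumerate([(cam_a, cam_b), (cam_b, cam_a)]):
        shot_cameras = [first, second, first]
        shots = []
        for shot_idx, cam_name in enumerate(shot_cameras):
            cam = cam_by_name[cam_name]
            spec = GelSceneSpec(
                shape=tuple(g.shape),
                concentrations=tuple(g.concentrations),
                band_row=g.band_row,
                band_sigma_rows=g.band_sigma_rows,
                band_sigma_cols=g.band_sigma_cols,
                band_peak=g.band_peak * g.fading_per_shot**shot_idx,
                background_level=g.background_level,
                noise_sigma=cam.noise_sigma,
                saturation=cam.saturation,
                seed=_derived_seed(config.seed, 1000 + exp_idx, shot_idx),
            )
            image, truth = generate_gel_image(spec)
            if config.write_images or not quantify:
                gio.write_image(
                    outdir / f"gel_exp{exp_idx + 1}_shot{shot_idx + 1}_{cam_name}.png",
                    image,
                    bit_depth=config.bit_depth,
                )
            if not quantify:
                continue
            rois = gio.read_rois(g.roi_file) if g.roi_file else default_rois(spec)
            volumes = [band_volume(image, roi, g.border_width) for roi in rois]
            concs = [roi.concentration for roi in rois]
            result = dilution_regression(volumes, concs, camera=cam_name, shot=shot_idx + 1)
            shots.append(result)
            for roi, vol, gt in zip(rois, volumes, truth):
                vol_rows.append(
                    {
                        "experiment": exp_idx + 1, "shot": shot_idx + 1,
                        "camera": cam_name, "lane": roi.lane,
                        "concentration": roi.concentration, "volume": vol,
                        "ground_truth_volume": gt, "seed": spec.seed,
                    }
                )
            reg_rows.append(
                {
                    "experiment": exp_idx + 1, "shot": shot_idx + 1, "camera": cam_name,
                    "slope": result.slope, "intercept": result.intercept,
                    "r2": result.r2, "snr": result.snr, "seed": spec.seed,
                }
            )
        if quantify:
            experiments.append(
                ExperimentComparison(
                    name=f"exp{exp_idx + 1}",
                    camera_a=first,
                    camera_b=second,
                    shots=tuple(shots),
                )
            )
    summary["gel"] = {"camera_a": cam_a, "camera_b": cam_b}
    if not quantify:
        return None
    pd.DataFrame(vol_rows).to_csv(outdir / "gel_volumes.csv", index=False)
    pd.DataFrame(reg_rows).to_csv(outdir / "gel_regression.csv", index=False)
    return experiments


def _run_compare(experiments, outdir, summary) -> None:
    reports, per_camera = compare_experiments(experiments)
    rows = []
    for rep in reports:
        for shot_idx, (r2, rank) in enumerate(zip(rep.shot_r2, rep.ranks), start=1):
            cam = rep.camera_a if shot_idx != 2 else rep.camera_b
            rows.append(
                {
                    "experiment": rep.name, "shot": shot_idx, "camera": cam,
                    "r2": r2, "rank": rank, "tie": rep.tie,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "gel_ranks.csv", index=False)
    summary["compare"] = {
        "experiments": [
            {
                "name": rep.name,
                "camera_a": rep.camera_a,
                "camera_b": rep.camera_b,
                "ranks": list(rep.ranks),
                "flank_mean": rep.flank_mean,
                "center_r2": rep.center_r2,
                "slope_ratio": rep.slope_ratio,
            }
            for rep in reports
        ],
        "per_camera_mean_r2": per_camera,
    }


def _render_plots(config, series_by_camera, scaling_by_camera, outdir, summary) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .linearity import reflectance_constancy, slope_vs_pwm, order_selection

    for name, series in series_by_camera.items():
        const = reflectance_constancy(series, config.fit_order)
        fig, ax = plt.subplots()
        for level, curve in sorted(const.fit_curves.items(), reverse=True):
            ax.plot(const.fit_grid, curve, label=f"PWM {int(level)}")
        for level, base in const.baseline_curves.items():
            ax.plot(const.baseline_grid, base, "r.", ms=4)
        ax.set(xlabel="normalized position t", ylabel="brightness (counts)", title=name)
        ax.legend(fontsize=7)
        fig.savefig(outdir / f"constancy_{name}.png", dpi=110)
        plt.close(fig)

    if series_by_camera:
        fig, ax = plt.subplots()
        for name, series in series_by_camera.items():
            sl = slope_vs_pwm(series)
            pwm = sorted(sl.slopes)
            ax.plot(pwm, [sl.slopes[p] for p in pwm], "o-", label=name)
        ax.set(xlabel="PWM duty", ylabel="first-order slope (counts)")
        ax.legend(fontsize=7)
        fig.savefig(outdir / "slope_vs_pwm.png", dpi=110)
        plt.close(fig)

        fig, axes = plt.subplots(1, len(series_by_camera), figsize=(4 * len(series_by_camera), 3))
        axes = np.atleast_1d(axes)
        for ax, (name, series) in zip(axes, series_by_camera.items()):
            sel = order_selection(series, config.max_order)
            for level, errs in sorted(sel.errors.items(), reverse=True):
                ax.plot(sel.orders, errs, "o-", label=f"PWM {int(level)}")
            ax.set(xlabel="order", ylabel="error (counts^2)", title=name)
            ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(outdir / "order_errors.png", dpi=110)
        plt.close(fig)

    if scaling_by_camera:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        for name, res in scaling_by_camera.items():
            levels = sorted(res.d, reverse=True)
            ax1.plot(levels, [res.d[l] for l in levels], "o-", label=name)
            ax2.plot(levels, [res.errors[l] for l in levels], "o-", label=name)
        levels = sorted(next(iter(scaling_by_camera.values())).baseline, reverse=True)
        ax1.plot(levels, [l / 100 for l in levels], "k--", label="d = PWM/100")
        ax1.set(xlabel="PWM duty", ylabel="constant d")
        ax2.set(xlabel="PWM duty", ylabel="error (counts^2)")
        ax1.legend(fontsize=7)
        ax2.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "scaling_constants.png", dpi=110)
        plt.close(fig)

    if "compare" in summary:
        fig, ax = plt.subplots()
        exps = summary["compare"]["experiments"]
        x = np.arange(len(exps))
        ax.bar(x - 0.15, [e["flank_mean"] for e in exps], width=0.3, label="flank mean R²")
        ax.bar(x + 0.15, [e["center_r2"] for e in exps], width=0.3, label="center R²")
        ax.set_xticks(x, [e["name"] for e in exps])
        ax.set_ylabel("R²")
        ax.legend(fontsize=7)
        fig.savefig(outdir / "flank_vs_center.png", dpi=110)
        plt.close(fig)


def demo_config(seed: int, output_dir: str = "gelcam_demo", *, plots: bool = False) -> RunConfig:
    """Full synthetic demo: four cameras of increasing gamma, all stages."""
    from .config import CameraConfig

    return RunConfig(
        stages=("simulate-gradient", "method1", "method2", "simulate-gel",
                "gel-quant", "compare"),
        seed=seed,
        output_dir=output_dir,
        cameras=(
            CameraConfig(name="cam_g1.0", gamma=1.0, noise_sigma=1.5),
            CameraConfig(name="cam_g1.1", gamma=1.1, noise_sigma=2.0),
            CameraConfig(name="cam_g1.3", gamma=1.3, noise_sigma=2.5),
            CameraConfig(name="cam_g1.6", gamma=1.6, noise_sigma=3.0),
        ),
        plots=plots,
    )
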