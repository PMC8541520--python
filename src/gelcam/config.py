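"""Run configuration: structured YAML with CLI-flag overrides.

A :class:`RunConfig` describes one pipeline run: which stages to execute,
simulator specs (or input paths), analysis settings, the mandatory seed for
any simulation stage, and output options.  The canonical on-disk form is a
YAML file mirroring the dataclass fields; every scalar can be overridden from
the command line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

__all__ = ["CameraConfig", "GelStageConfig", "RunConfig", "load_config", "STAGES"]

STAGES = ("simulate-gradient", "method1", "method2", "simulate-gel", "gel-quant", "compare")


@dataclass
class CameraConfig:
    """Simulator parameters of one camera under evaluation."""

    name: str
    gain: float = 230.0
    gamma: float = 1.0
    offset: float = 0.0
    noise_sigma: float = 2.0
    saturation: float = 255.0


@dataclass
class GelStageConfig:
    """Gel-stage settings: scene geometry and the alternating-shot design."""

    shape: tuple[int, int] = (200, 400)
    concentrations: tuple[float, ...] = (1.0, 0.5, 0.2, 0.1, 0.05)
    band_peak: float = 180.0
    background_level: float = 30.0
    band_row: int = 100
    band_sigma_rows: float = 6.0
    band_sigma_cols: float = 10.0
    roi_file: str | None = None  # annotation CSV; default ROIs from geometry if None
    border_width: int = 3
    fading_per_shot: float = 1.0  # band_peak multiplier per successive shot (1 = none)


@dataclass
class RunConfig:
    """Full pipeline configuration.

    ``seed`` is mandatory whenever a simulation stage is selected.  Gradient
    images can come either from the simulator (``cameras``) or from a
    directory of files named ``{camera}_pwm{level}.png`` (``gradient_dir``).
    """

    stages: tuple[str, ...] = ()
    seed: int | None = None
    output_dir: str = "gelcam_out"
    cameras: tuple[CameraConfig, ...] = ()
    gradient_dir: str | None = None
    pwm_levels: tuple[float, ...] = (100, 80, 60, 40, 20)
    image_shape: tuple[int, int] = (64, 256)
    spatial_coeffs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)
    fit_order: int = 3
    max_order: int = 6
    gel: GelStageConfig = field(default_factory=GelStageConfig)
    bit_depth: int = 8
    plots: bool = False
    write_images: bool = False

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("no stages selected")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        simulating = {"simulate-gradient", "simulate-gel"} & set(self.stages)
        if simulating and self.seed is None:
            raise ValueError("seed is mandatory for simulation stages")
        needs_gradient = {"method1", "method2"} & set(self.stages)
        if needs_gradient and "simulate-gradient" not in self.stages and not self.gradient_dir:
            raise ValueError(
                "method1/method2 need gradient images: select simulate-gradient "
                "or provide gradient_dir"
            )
        if "gel-quant" in self.stages and "simulate-gel" not in self.stages:
            raise ValueError("gel-quant needs gel images: select simulate-gel")
        if "compare" in self.stages and "gel-quant" not in self.stages:
            raise ValueError("compare needs gel-quant results")
        if self.gel.roi_file is not None and not Path(self.gel.roi_file).exists():
            raise ValueError(f"roi_file does not exist: {self.gel.roi_file}")
        if self.gradient_dir is not None and not Path(self.gradient_dir).exists():
            raise ValueError(f"gradient_dir does not exist: {self.gradient_dir}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _tupled(value: Any) -> Any:
    return tuple(value) if isinstance(value, list) else value


def load_config(path: str | Path | None = None, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus flat overrides.

    Override keys use the dataclass field names; gel-stage fields are nested
    under ``gel`` in the file or prefixed ``gel_`` in overrides.
    """
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        data.update(loaded)
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key.startswith("gel_"):
            data.setdefault("gel", {})
            if isinstance(data["gel"], dict):
                data["gel"][key[4:]] = value
        else:
            data[key] = value

    gel_raw = data.pop("gel", {}) or {}
    gel = GelStageConfig(**{k: _tupled(v) for k, v in gel_raw.items()})
    cameras = tuple(
        CameraConfig(**cam) if isinstance(cam, dict) else cam
        for cam in data.pop("cameras", ())
    )
    cfg = RunConfig(
        cameras=cameras,
        gel=gel,
        **{k: _tupled(v) for k, v in data.items()},
    )
    # shape-like fields arrive as lists from YAML
    cfg.stages = tuple(cfg.stages)
    cfg.pwm_levels = tuple(float(x) for x in cfg.pwm_levels)
    cfg.image_shape = tuple(int(x) for x in cfg.image_shape)
    cfg.spatial_coeffs = tuple(float(x) for x in cfg.spatial_coeffs)
    return cfg
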