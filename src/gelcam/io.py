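"""File I/O: images, ROI/corner annotation CSVs, ground-truth sidecars.

Images circulate in memory as float64 count arrays; on disk they are 8-bit
PNG (saturation 255) or 16-bit TIFF (saturation 65535), chosen by extension.
Annotation files are plain CSV so they can be produced by hand or by any
annotation tool.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .gel import BandROI, CornerQuad

__all__ = [
    "write_image",
    "read_image",
    "read_rois",
    "write_rois",
    "read_corners",
    "write_corners",
    "write_ground_truth",
    "read_ground_truth",
]

ROI_COLUMNS = ["lane", "row0", "col0", "row1", "col1", "concentration"]
CORNER_COLUMNS = ["label", "x", "y"]
CORNER_ORDER = ["top_left", "top_right", "bottom_right", "bottom_left"]


def write_image(path: str | Path, image: np.ndarray, *, bit_depth: int = 8) -> Path:
    """Quantize a float count image and write it as PNG (8-bit) or TIFF (16-bit)."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as a float64 count array (PNG or TIFF)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return np.asarray(arr, dtype=float)


def write_rois(path: str | Path, rois: Sequence[BandROI]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "lane": r.lane, "row0": r.row0, "col0": r.col0,
                "row1": r.row1, "col1": r.col1, "concentration": r.concentration,
            }
            for r in rois
        ],
        columns=ROI_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def read_rois(path: str | Path) -> list[BandROI]:
    """Read band ROIs from CSV (columns lane,row0,col0,row1,col1,concentration)."""
    df = pd.read_csv(path)
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI file missing columns: {sorted(missing)}")
    return [
        BandROI(
            lane=int(row.lane), row0=int(row.row0), col0=int(row.col0),
            row1=int(row.row1), col1=int(row.col1),
            concentration=float(row.concentration),
        )
        for row in df.itertuples()
    ]


def write_corners(path: str | Path, quad: CornerQuad) -> Path:
    path = Path(path)
    rows = [
        {"label": label, "x": x, "y": y}
        for label, (x, y) in zip(CORNER_ORDER, quad.corners)
    ]
    rows.append({"label": "target_size", "x": quad.target_width, "y": quad.target_height})
    pd.DataFrame(rows, columns=CORNER_COLUMNS).to_csv(path, index=False)
    return path


def read_corners(path: str | Path) -> CornerQuad:
    """Read a 4-corner annotation CSV (labels top_left..bottom_left + target_size)."""
    df = pd.read_csv(path).set_index("label")
    try:
        corners = tuple(
            (float(df.loc[label, "x"]), float(df.loc[label, "y"]))
            for label in CORNER_ORDER
        )
        tw, th = int(df.loc["target_size", "x"]), int(df.loc["target_size", "y"])
    except KeyError as exc:
        raise ValueError(f"corner file missing row: {exc}") from exc
    return CornerQuad(corners=corners, target_width=tw, target_height=th)


def write_ground_truth(path: str | Path, payload: dict) -> Path:
    """Write a JSON sidecar (ground-truth volumes, corners, model parameters)."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
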