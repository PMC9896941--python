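"""TIFF/CSV/YAML interchange with the fixed T,Z,C,Y,X axis convention."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

AXES = "TZCYX"


def write_hyperstack(
    path: str | Path,
    movie_tczyx: np.ndarray,
    voxel_size_nm: Tuple[float, float, float],
) -> None:
    """Write a (T, C, Z, Y, X) float movie as a 16-bit TZCYX hyperstack.

    Counts are clipped to the uint16 range; voxel size (z, y, x nm) is
    recorded in the ImageJ-style metadata (resolution in pixels/µm laterally,
    spacing in µm axially).
    """
    movie = np.asarray(movie_tczyx)
    if movie.ndim != 5:
        raise ValueError("expected (T, C, Z, Y, X)")
    data = np.clip(np.rint(movie), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    data = np.moveaxis(data, 1, 2)  # -> T, Z, C, Y, X
    vz, vy, vx = voxel_size_nm
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1000.0 / vx, 1000.0 / vy),
        metadata={"axes": AXES, "spacing": vz / 1000.0, "unit": "um"},
    )


def read_hyperstack(path: str | Path) -> Tuple[np.ndarray, Optional[Tuple[float, float, float]]]:
    """Read a TZCYX hyperstack; returns ((T, C, Z, Y, X) float array, voxel size nm)."""
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        voxel = None
        try:
            ij = tf.imagej_metadata or {}
            spacing_um = float(ij.get("spacing", 0.0))
            page = tf.pages[0]
            xres = page.tags["XResolution"].value
            vx = 1000.0 * xres[1] / xres[0]
            yres = page.tags["YResolution"].value
            vy = 1000.0 * yres[1] / yres[0]
            if spacing_um > 0:
                voxel = (spacing_um * 1000.0, vy, vx)
        except (KeyError, TypeError, ZeroDivisionError):
            logger.warning("voxel size metadata missing in %s", path)
    # normalize axes to T, Z, C, Y, X then move to T, C, Z, Y, X
    for missing in set(AXES) - set(axes):
        data = data[np.newaxis]
        axes = missing + axes
    order = [axes.index(a) for a in AXES]
    data = np.transpose(data, order)
    return np.moveaxis(data.astype(np.float64), 2, 1), voxel


def write_labels(path: str | Path, labels_tzyx: np.ndarray) -> None:
    tifffile.imwrite(
        str(path),
        np.asarray(labels_tzyx, dtype=np.uint16),
        imagej=True,
        metadata={"axes": "TZYX"},
    )


def write_float_map(path: str | Path, img: np.ndarray) -> None:
    """32-bit float TIFF, used for local-SSIM maps."""
    tifffile.imwrite(str(path), np.asarray(img, dtype=np.float32))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir: str | Path, cfg: dict, seed: int, inputs: list[str]) -> Path:
    """Provenance manifest written next to every stage's outputs."""
    import polqc

    manifest = {
        "config_hash": config_hash(cfg),
        "config": cfg,
        "seed": seed,
        "inputs": inputs,
        "polqc_version": polqc.__version__,
        "numpy_version": np.__version__,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
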