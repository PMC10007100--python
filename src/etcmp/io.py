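"""Reading and writing scenes and tables.

Scenes are stored as one multiband TIFF (one page per band, band order in
the JSON sidecar) plus a ``scene.json`` sidecar with the scalar metadata
(acquisition time, solar zenith, latitude, pixel size, and any derived
scalars such as emissivities). Tables are plain CSV.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .rs_preprocess import SpectralScene

__all__ = ["write_scene", "read_scene", "write_raster_stack", "read_raster_stack"]


def write_raster_stack(path, arrays: dict[str, np.ndarray], meta: dict | None = None):
    """Write named 2D rasters as a multiband TIFF + JSON sidecar."""
    path = Path(path)
    names = list(arrays)
    stack = np.stack([np.asarray(arrays[k], dtype="float32") for k in names])
    tifffile.imwrite(path, stack)
    sidecar = {"bands": names, **(meta or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=str))


def read_raster_stack(path):
    """Read a multiband TIFF + sidecar back into ({name: array}, meta)."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    names = meta.pop("bands")
    return {n: stack[i].astype(float) for i, n in enumerate(names)}, meta


def write_scene(directory, scene: SpectralScene) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = dict(scene.reflectance)
    arrays["Ts"] = scene.surface_temperature
    write_raster_stack(directory / "scene.tif", arrays, {
        "acquisition_time": scene.acquisition_time.isoformat(),
        "solar_zenith": scene.solar_zenith,
        "latitude": scene.latitude,
        "pixel_size": scene.pixel_size,
    })


def read_scene(directory) -> SpectralScene:
    directory = Path(directory)
    arrays, meta = read_raster_stack(directory / "scene.tif")
    ts = arrays.pop("Ts")
    return SpectralScene(
        reflectance=arrays,
        surface_temperature=ts,
        acquisition_time=datetime.fromisoformat(meta["acquisition_time"]),
        solar_zenith=float(meta["solar_zenith"]),
        latitude=float(meta["latitude"]),
        pixel_size=float(meta.get("pixel_size", 30.0)),
    )


def read_forcing(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df


def write_table(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
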