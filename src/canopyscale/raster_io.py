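"""Raster and table serialization.

Rasters are written as single-band TIFF files with the georeferencing
(cell size, origin, EPSG code, nodata) embedded as a JSON document in the
TIFF ImageDescription tag, so a stack round-trips without sidecar files.
Tables go to plain CSV; configurations to YAML.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, is_dataclass

import numpy as np
import tifffile
import yaml

__all__ = ["write_raster", "read_raster", "write_stack", "save_yaml", "load_yaml"]


def write_raster(
    path,
    grid: np.ndarray,
    cell_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
    epsg: int | None = None,
    nodata: float = float("nan"),
) -> str:
    """Write one grid as a TIFF with JSON georeferencing metadata.

    ``origin`` is the (x, y) of the lower-left corner; row 0 of the grid is
    the north edge.
    """
    meta = {
        "cell_size": float(cell_size),
        "origin": [float(origin[0]), float(origin[1])],
        "epsg": epsg,
        "nodata": None if np.isnan(nodata) else float(nodata),
    }
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        np.asarray(grid, dtype=np.float32),
        description=json.dumps(meta),
    )
    return str(path)


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read a grid and its georeferencing metadata written by write_raster."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        grid = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return np.asarray(grid), meta


def write_stack(outdir, grids: dict[str, np.ndarray], cell_size, epsg=None) -> list[str]:
    """Write a named stack of co-registered grids, one TIFF per grid."""
    outdir = pathlib.Path(outdir)
    return [
        write_raster(outdir / f"{name}.tif", grid, cell_size, epsg=epsg)
        for name, grid in grids.items()
    ]


def save_yaml(obj, path) -> str:
    """Serialize a (possibly dataclass) configuration to YAML."""
    data = asdict(obj) if is_dataclass(obj) else obj
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return str(path)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
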