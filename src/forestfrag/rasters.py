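"""Raster and point-table I/O.

Two raster dialects are accepted: Esri-style headered ASCII grids
(``.asc``/``.txt``) and plain single-band TIFF (``.tif``/``.tiff``, read
with tifffile).  ASCII grids carry cell size and origin in their header;
TIFFs do not reliably, so the cell size must be supplied by the caller.
Coordinates are assumed to be projected with meter units throughout —
geographic rasters are refused where detectable, never reprojected.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile

from .landscape import BinaryLandscape

_ASCII_EXTS = {".asc", ".txt", ".grd"}
_TIFF_EXTS = {".tif", ".tiff"}


def read_ascii_grid(path) -> tuple[np.ndarray, float, tuple[float, float], float | None]:
    """Read an Esri ASCII grid.

    Returns ``(values, cell_size, (x_min, y_max), nodata)`` with rows
    ordered top to bottom as in the file.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} is missing header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell_size = header["cellsize"]
    if cell_size < 0.1:
        raise ValueError(
            f"cellsize {cell_size} looks like degrees, not meters; "
            "reproject to a meter-unit CRS first"
        )
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"grid body shape {values.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    if "xllcorner" in header and "yllcorner" in header:
        origin = (header["xllcorner"], header["yllcorner"] + nrows * cell_size)
    elif "xllcenter" in header and "yllcenter" in header:
        origin = (
            header["xllcenter"] - cell_size / 2,
            header["yllcenter"] - cell_size / 2 + nrows * cell_size,
        )
    else:
        origin = (0.0, nrows * cell_size)
    return values, cell_size, origin, header.get("nodata_value")


def write_ascii_grid(
    values: np.ndarray,
    path,
    cell_size: float,
    origin: tuple[float, float] | None = None,
    nodata: float = -9999,
    fmt: str = "%d",
) -> None:
    """Write a 2-D array as an Esri ASCII grid."""
    values = np.asarray(values)
    nrows, ncols = values.shape
    if origin is None:
        x_min, y_max = 0.0, nrows * cell_size
    else:
        x_min, y_max = origin
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x_min:g}\n")
        fh.write(f"yllcorner {y_max - nrows * cell_size:g}\n")
        fh.write(f"cellsize {cell_size:g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, values, fmt=fmt)


def read_raster(
    path, cell_size: float | None = None, origin: tuple[float, float] | None = None
) -> tuple[np.ndarray, float, tuple[float, float] | None]:
    """Read a raster as ``(values, cell_size, origin)``, dispatching on extension.

    ASCII grids supply their own cell size and origin (overridable);
    TIFFs require ``cell_size`` from the caller.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext in _ASCII_EXTS:
        values, cs, orig, nodata = read_ascii_grid(path)
        if nodata is not None:
            values = np.where(values == nodata, np.nan, values)
        return values, cell_size or cs, origin or orig
    if ext in _TIFF_EXTS:
        values = np.asarray(tifffile.imread(path), dtype=float)
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster")
        if cell_size is None:
            raise ValueError(f"{path}: cell_size is required for TIFF rasters")
        return values, cell_size, origin
    raise ValueError(f"unsupported raster extension {ext!r} for {path}")


def load_binary_landscape(
    path,
    cell_size: float | None = None,
    origin: tuple[float, float] | None = None,
    threshold: float | None = None,
) -> BinaryLandscape:
    """Load a raster as a binary landscape.

    Values must already be {0, 1} unless ``threshold`` is given, in which
    case the raster is treated as tree heights in meters and thresholded
    (>= threshold is habitat).  NaN / nodata cells become non-habitat.
    """
    values, cs, orig = read_raster(path, cell_size, origin)
    if threshold is not None:
        habitat = np.nan_to_num(values, nan=-np.inf) >= threshold
    else:
        finite = values[np.isfinite(values)]
        if not np.isin(finite, (0, 1)).all():
            raise ValueError(
                f"{path}: values are not binary; pass threshold= for height rasters"
            )
        habitat = np.nan_to_num(values, nan=0) == 1
    return BinaryLandscape(habitat.astype(np.int8), cs, origin=orig)


def read_points(path) -> pd.DataFrame:
    """Read a sample-point table (CSV with columns id, x, y and optional biome)."""
    pts = pd.read_csv(path)
    missing = {"id", "x", "y"} - set(pts.columns)
    if missing:
        raise ValueError(f"points table {path} is missing columns: {sorted(missing)}")
    if "biome" not in pts.columns:
        pts["biome"] = "unknown"
    return pts
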