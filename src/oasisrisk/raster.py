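"""Minimal georeferenced raster container and I/O.

A :class:`Raster` is a 2-D array (continuous or categorical) with a nodata
sentinel, a square cell size in metres, and a top-left origin.  Row 0 is the
northernmost row; cells follow the half-open pixel convention (a point
belongs to the cell whose index is ``floor`` of its offset in cells).

Supported on-disk formats are ESRI ASCII grid (``.asc``/``.txt``) and
single-band TIFF (``.tif``/``.tiff``).  ASCII grids carry cell size, origin
and nodata in their header; plain TIFF carries values only, so a raster
read from TIFF defaults to a unit cell size unless the caller supplies one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Raster", "read_raster", "write_raster", "RasterIOError"]


class RasterIOError(ValueError):
    """Raised for malformed raster files or unsupported layouts."""


@dataclass
class Raster:
    """Single-band raster with nodata mask and square-cell georeferencing.

    Parameters
    ----------
    data : ndarray, shape (rows, cols)
        Cell values. Nodata cells hold ``nodata`` (categorical) or may be
        NaN (continuous).
    cell_size : float
        Side length of a cell in metres.
    nodata : float or int, optional
        Sentinel value marking cells outside the study area.
    origin : (float, float)
        (x, y) of the outer corner of cell (0, 0); y decreases downwards.
    """

    data: np.ndarray
    cell_size: float = 1.0
    nodata: float | int | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise RasterIOError(
                f"raster must be a single 2-D band, got shape {self.data.shape}"
            )
        if self.cell_size <= 0:
            raise RasterIOError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        valid = np.ones(self.data.shape, dtype=bool)
        if self.nodata is not None:
            valid &= self.data != self.nodata
        if np.issubdtype(self.data.dtype, np.floating):
            valid &= ~np.isnan(self.data)
        return valid

    def values(self) -> np.ndarray:
        """1-D array of valid cell values."""
        return self.data[self.mask()]

    def like(self, data: np.ndarray, nodata=None) -> "Raster":
        """New raster sharing this raster's georeferencing."""
        return Raster(
            data,
            cell_size=self.cell_size,
            nodata=self.nodata if nodata is None else nodata,
            origin=self.origin,
        )


def _read_ascii_grid(path: Path) -> Raster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            }:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    if "ncols" not in header or "nrows" not in header:
        raise RasterIOError(f"{path}: missing ncols/nrows header")
    data = np.array(rows)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        data = data.reshape(nrows, ncols)
    cell = header.get("cellsize", 1.0)
    nodata = header.get("nodata_value")
    if np.all(data == np.floor(data)) and np.abs(data).max(initial=0) < 2**31:
        idata = data.astype(np.int64)
        # keep integer rasters integer so categorical round-trips are exact
        if nodata is None or float(nodata) == int(nodata):
            data = idata
            nodata = None if nodata is None else int(nodata)
    xll = header.get("xllcorner", header.get("xllcenter", 0.0))
    yll = header.get("yllcorner", header.get("yllcenter", 0.0))
    origin = (xll, yll + nrows * cell)
    return Raster(data, cell_size=cell, nodata=nodata, origin=origin)


def _write_ascii_grid(raster: Raster, path: Path) -> None:
    nrows, ncols = raster.shape
    nodata = raster.nodata
    data = raster.data
    if np.issubdtype(data.dtype, np.floating) and np.isnan(data).any():
        nodata = -9999.0 if nodata is None else nodata
        data = np.where(np.isnan(data), nodata, data)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]}\n")
        fh.write(f"yllcorner {raster.origin[1] - nrows * raster.cell_size}\n")
        fh.write(f"cellsize {raster.cell_size}\n")
        if nodata is not None:
            fh.write(f"NODATA_value {nodata}\n")
        if np.issubdtype(data.dtype, np.integer):
            np.savetxt(fh, data, fmt="%d")
        else:
            np.savetxt(fh, data, fmt="%.8g")


def read_raster(path: str | Path, cell_size: float | None = None) -> Raster:
    """Read a single-band raster from ASCII grid or TIFF.

    Round-trips are bit-exact for integer rasters and float32-exact for
    continuous rasters.  TIFF files carry no georeferencing here; a missing
    cell size falls back to 1 m with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in {".asc", ".txt", ".grd"}:
        r = _read_ascii_grid(path)
        if cell_size is not None:
            r.cell_size = cell_size
        return r
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise RasterIOError(
                f"{path}: expected a single band, got shape {arr.shape}"
            )
        if cell_size is None:
            warnings.warn(
                f"{path}: TIFF has no georeferencing; assuming 1 m cells",
                stacklevel=2,
            )
            cell_size = 1.0
        nodata = None
        if arr.dtype == np.uint8 and (arr == 255).any():
            nodata = 255
        return Raster(arr, cell_size=cell_size, nodata=nodata)
    raise RasterIOError(f"unsupported raster format: {path.suffix!r}")


def write_raster(raster: Raster, path: str | Path) -> None:
    """Write to ASCII grid or single-band TIFF, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() in {".asc", ".txt", ".grd"}:
        _write_ascii_grid(raster, path)
        return
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = raster.data
        if np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        elif data.dtype != np.uint8 and data.max(initial=0) < 256 and data.min(initial=0) >= 0:
            data = data.astype(np.uint8)
        tifffile.imwrite(path, data)
        return
    raise RasterIOError(f"unsupported raster format: {path.suffix!r}")
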