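"""Gridded environmental layers and plain-text raster I/O.

A :class:`ClimateGrid` is a stack of co-registered single-band rasters
(one per bioclimatic variable) over a named study region, in a simple
north-up, row-major, regular lon/lat grid.  Cells follow the half-open
convention ``[x, x + w) x (y - h, y]``: a point on the western/northern
edge of a cell belongs to that cell.

On-disk formats are ESRI ASCII grid (``.asc``, one file per variable,
file name = variable name) and single-band GeoTIFF written through
:mod:`tifffile` with ``ModelPixelScale`` / ``ModelTiepoint`` tags.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

NODATA = -9999.0

__all__ = [
    "ClimateGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
]


@dataclass
class ClimateGrid:
    """Co-registered environmental raster layers over one study region.

    Parameters
    ----------
    layers
        Mapping from variable name (e.g. ``"bio1"``) to a 2-D float array
        of shape ``(nrows, ncols)``.  Missing data are ``NaN``.
    x_origin, y_origin
        Longitude of the west edge and latitude of the north edge of the
        grid, in decimal degrees.
    cell_size
        Cell width/height in decimal degrees (square cells).
    region
        Free-text region label, e.g. ``"native"`` or ``"introduced"``.
    """

    layers: Dict[str, np.ndarray]
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 0.05
    region: str = ""

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("ClimateGrid requires at least one layer")
        shapes = {np.asarray(a).shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError(f"layers are not co-registered: shapes {shapes}")
        (shape,) = shapes
        if len(shape) != 2 or min(shape) < 1:
            raise ValueError(f"layers must be non-empty 2-D arrays, got shape {shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_cells(self) -> int:
        r, c = self.shape
        return r * c

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape ``shape`` giving each cell's center."""
        r, c = self.shape
        lon = self.x_origin + (np.arange(c) + 0.5) * self.cell_size
        lat = self.y_origin - (np.arange(r) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def rowcol(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points.

        Uses floor arithmetic with half-open cells; indices may fall
        outside the grid (use :meth:`inside` to check).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_origin) / self.cell_size).astype(int)
        # latitude decreases with row; cell r covers lat in (y0-(r+1)h, y0-r*h]
        row = np.floor((self.y_origin - lat) / self.cell_size).astype(int)
        return row, col

    def inside(self, row, col) -> np.ndarray:
        r, c = self.shape
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < r) & (col >= 0) & (col < c)

    # ------------------------------------------------------------------ values
    def stack(self) -> np.ndarray:
        """Layers as a ``(n_layers, nrows, ncols)`` array."""
        return np.stack([self.layers[k] for k in self.layer_names])

    def env_table(self, dropna: bool = True) -> pd.DataFrame:
        """One row per cell, one column per variable; index = flat cell id.

        With ``dropna=True`` (default) cells with missing data in any
        layer are excluded.
        """
        data = {k: self.layers[k].ravel() for k in self.layer_names}
        df = pd.DataFrame(data)
        if dropna:
            df = df.dropna()
        return df

    def coords_table(self) -> pd.DataFrame:
        """lon/lat of every cell center; index = flat cell id."""
        lon, lat = self.cell_centers()
        return pd.DataFrame({"lon": lon.ravel(), "lat": lat.ravel()})

    def values_at(self, lon, lat) -> tuple[pd.DataFrame, np.ndarray]:
        """Extract all layer values at point locations.

        Returns ``(values, inside)`` where ``values`` has one row per
        input point (NaN outside the grid) and ``inside`` flags points
        whose containing cell lies within the extent.
        """
        row, col = self.rowcol(lon, lat)
        ok = self.inside(row, col)
        r = np.where(ok, row, 0)
        c = np.where(ok, col, 0)
        out = {}
        for name in self.layer_names:
            v = self.layers[name][r, c]
            out[name] = np.where(ok, v, np.nan)
        return pd.DataFrame(out), ok

    # ------------------------------------------------------------------ I/O
    def to_ascii_dir(self, path: str | os.PathLike) -> None:
        """Write one ``<variable>.asc`` per layer into a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in self.layer_names:
            write_ascii_grid(
                path / f"{name}.asc",
                self.layers[name],
                self.x_origin,
                self.y_origin,
                self.cell_size,
            )

    @classmethod
    def from_ascii_dir(
        cls, path: str | os.PathLike, region: str = ""
    ) -> "ClimateGrid":
        path = Path(path)
        files = sorted(path.glob("*.asc"), key=_bio_sort_key)
        if not files:
            raise FileNotFoundError(f"no .asc rasters found in {path}")
        layers = {}
        geo = None
        for f in files:
            arr, x0, y0, cs = read_ascii_grid(f)
            if geo is None:
                geo = (x0, y0, cs)
            elif not np.allclose(geo, (x0, y0, cs)):
                raise ValueError(f"raster {f.name} is not co-registered")
            layers[f.stem] = arr
        x0, y0, cs = geo
        return cls(layers, x0, y0, cs, region=region)

    def to_geotiff_dir(self, path: str | os.PathLike) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in self.layer_names:
            write_geotiff(
                path / f"{name}.tif",
                self.layers[name],
                self.x_origin,
                self.y_origin,
                self.cell_size,
            )


def _bio_sort_key(p: Path):
    stem = p.stem
    if stem.startswith("bio") and stem[3:].isdigit():
        return (0, int(stem[3:]))
    return (1, stem)


# ---------------------------------------------------------------------- ASCII
def write_ascii_grid(
    path: str | os.PathLike,
    array: np.ndarray,
    x_origin: float,
    y_origin: float,
    cell_size: float,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (NaN -> NODATA)."""
    array = np.asarray(array, dtype=float)
    nrows, ncols = array.shape
    yll = y_origin - nrows * cell_size
    out = np.where(np.isfinite(array), array, NODATA)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x_origin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | os.PathLike) -> tuple[np.ndarray, float, float, float]:
    """Read an ESRI ASCII grid; returns (array, x_origin, y_origin, cell_size)."""
    header: Dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        arr = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {key!r}")
    nodata = header.get("nodata_value", NODATA)
    arr = np.where(np.isclose(arr, nodata), np.nan, arr)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data shape {arr.shape} disagrees with header")
    cs = header["cellsize"]
    x0 = header["xllcorner"]
    y0 = header["yllcorner"] + int(header["nrows"]) * cs
    return arr, x0, y0, cs


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------- GeoTIFF
def write_geotiff(
    path: str | os.PathLike,
    array: np.ndarray,
    x_origin: float,
    y_origin: float,
    cell_size: float,
) -> None:
    """Write a single-band float32 GeoTIFF with basic geo-referencing tags."""
    import tifffile

    array = np.asarray(array, dtype=np.float32)
    extratags = [
        (33550, "d", 3, (cell_size, cell_size, 0.0)),  # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, x_origin, y_origin, 0.0)),  # ModelTiepoint
    ]
    tifffile.imwrite(path, array, extratags=extratags)


def read_geotiff(path: str | os.PathLike) -> tuple[np.ndarray, float, float, float]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray().astype(float)
        scale = page.tags.get(33550)
        tiepoint = page.tags.get(33922)
        if scale is None or tiepoint is None:
            raise ValueError(f"{path}: no geo-referencing tags")
        cs = float(scale.value[0])
        x0 = float(tiepoint.value[3])
        y0 = float(tiepoint.value[4])
    return arr, x0, y0, cs
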