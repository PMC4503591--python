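"""Regular lon/lat raster grids and named, co-registered raster stacks.

Coordinates are WGS84 decimal degrees. Cells are half-open
``[west, west + res) x [south, south + res)`` and values are attributed to
cell centers at ``origin + (i + 0.5) * res``. Raster I/O uses the ESRI
ASCII grid format (plain text), one file per layer.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "RasterStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_occurrences",
    "write_occurrences",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat lattice.

    Parameters
    ----------
    west, south : float
        Coordinates of the outer corner of the south-western cell (degrees).
    resolution : float
        Cell size in degrees; must be positive.
    nx, ny : int
        Number of columns (longitudes) and rows (latitudes).
    """

    west: float
    south: float
    resolution: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("grid resolution must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid extent is empty")

    @property
    def east(self) -> float:
        return self.west + self.nx * self.resolution

    @property
    def north(self) -> float:
        return self.south + self.ny * self.resolution

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes, west to east."""
        return self.west + (np.arange(self.nx) + 0.5) * self.resolution

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, south to north."""
        return self.south + (np.arange(self.ny) + 0.5) * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.west)
            & (lon < self.east)
            & (lat >= self.south)
            & (lat < self.north)
        )

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices; caller checks containment."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ix = np.floor((lon - self.west) / self.resolution).astype(int)
        iy = np.floor((lat - self.south) / self.resolution).astype(int)
        return iy, ix

    def cell_center(self, iy, ix) -> tuple[np.ndarray, np.ndarray]:
        lon = self.west + (np.asarray(ix) + 0.5) * self.resolution
        lat = self.south + (np.asarray(iy) + 0.5) * self.resolution
        return lon, lat

    def flat_index(self, iy, ix) -> np.ndarray:
        return np.asarray(iy) * self.nx + np.asarray(ix)


@dataclass
class RasterStack:
    """Named, co-registered 2-D layers on a shared :class:`GridSpec`.

    Layers are ``(ny, nx)`` float arrays with row 0 at the southern edge.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}"
                )
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def add(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError("layer shape mismatch")
        self.layers[name] = values

    def copy(self) -> "RasterStack":
        return RasterStack(self.grid, {k: v.copy() for k, v in self.layers.items()})

    def subset(self, names) -> "RasterStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"predictors not in stack: {missing}")
        return RasterStack(self.grid, {n: self.layers[n] for n in names})

    def to_frame(self, names=None) -> pd.DataFrame:
        """Flatten to a cells x predictors table (row-major, south row first)."""
        names = self.names if names is None else list(names)
        return pd.DataFrame({n: self.subset([n])[n].ravel() for n in names})

    def extract(self, lons, lats, names=None) -> pd.DataFrame:
        """Predictor vectors at the cells containing the given points."""
        names = self.names if names is None else list(names)
        inside = self.grid.contains(lons, lats)
        if not np.all(inside):
            raise ValueError("points outside grid extent")
        iy, ix = self.grid.cell_index(lons, lats)
        return pd.DataFrame({n: self.layers[n][iy, ix] for n in names})


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(path, grid: GridSpec, values: np.ndarray, nodata: float = -9999.0) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    out = np.where(np.isfinite(values), values, nodata)
    buf = io.StringIO()
    buf.write(f"ncols {grid.nx}\n")
    buf.write(f"nrows {grid.ny}\n")
    buf.write(f"xllcorner {grid.west!r}\n")
    buf.write(f"yllcorner {grid.south!r}\n")
    buf.write(f"cellsize {grid.resolution!r}\n")
    buf.write(f"NODATA_value {nodata!r}\n")
    # ESRI convention: first data row is the northern edge
    np.savetxt(buf, out[::-1], fmt="%.10g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    grid = GridSpec(
        west=header["xllcorner"],
        south=header["yllcorner"],
        resolution=header["cellsize"],
        nx=int(header["ncols"]),
        ny=int(header["nrows"]),
    )
    data = np.loadtxt(io.StringIO("".join(lines[n_header:])))
    data = np.atleast_2d(data)[::-1]
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return grid, data


def write_stack(directory, stack: RasterStack) -> None:
    os.makedirs(directory, exist_ok=True)
    for name, arr in stack.layers.items():
        write_ascii_grid(os.path.join(directory, f"{name}.asc"), stack.grid, arr)


def read_stack(directory) -> RasterStack:
    layers = {}
    grid = None
    for fname in sorted(os.listdir(directory)):
        if not fname.endswith(".asc"):
            continue
        g, arr = read_ascii_grid(os.path.join(directory, fname))
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError("layers are not co-registered")
        layers[fname[:-4]] = arr
    if grid is None:
        raise ValueError(f"no .asc layers found in {directory}")
    return RasterStack(grid, layers)


# ---------------------------------------------------------------------------
# Occurrence CSV I/O ("lon,lat" header)


def write_occurrences(path, points: pd.DataFrame) -> None:
    points[["lon", "lat"]].to_csv(path, index=False)


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"lon", "lat"} <= set(df.columns):
        raise ValueError("occurrence CSV must have 'lon' and 'lat' columns")
    return df[["lon", "lat"]].astype(float)
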