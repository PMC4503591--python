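"""Occurrence gridding, raster regridding, climatological summaries, and the
rank-correlation screen defining admissible predictor combinations."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from nichegen.grids import GridSpec, RasterStack

__all__ = [
    "grid_occurrences",
    "regrid_bilinear",
    "seasonal_summary",
    "spearman_screen",
    "enumerate_combos",
]


def grid_occurrences(points: pd.DataFrame, grid: GridSpec) -> tuple[pd.DataFrame, int]:
    """Snap occurrence points to the grid, one record per occupied cell.

    Multiple records in a cell collapse to a single record at the cell
    center (reduces spatial autocorrelation before model fitting). Returns
    ``(gridded points, n_dropped)`` where dropped points fell outside the
    grid extent.
    """
    if points.empty:
        raise ValueError("no occurrence points supplied")
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    inside = grid.contains(lon, lat)
    n_dropped = int((~inside).sum())
    iy, ix = grid.cell_index(lon[inside], lat[inside])
    occupied = np.unique(grid.flat_index(iy, ix))
    oy, ox = np.divmod(occupied, grid.nx)
    clon, clat = grid.cell_center(oy, ox)
    return pd.DataFrame({"lon": clon, "lat": clat}), n_dropped


def regrid_bilinear(
    source_grid: GridSpec, values: np.ndarray, target_grid: GridSpec
) -> np.ndarray:
    """Bilinear interpolation from source cell centers onto target centers.

    Target cell centers beyond the outermost source centers use
    nearest-edge extension; target grids disjoint from the source raise.
    """
    if (
        target_grid.west >= source_grid.east
        or target_grid.east <= source_grid.west
        or target_grid.south >= source_grid.north
        or target_grid.north <= source_grid.south
    ):
        raise ValueError("target grid extent is disjoint from source")
    values = np.asarray(values, dtype=float)
    src_lon = source_grid.lons
    src_lat = source_grid.lats
    tx = np.clip(target_grid.lons, src_lon[0], src_lon[-1])
    ty = np.clip(target_grid.lats, src_lat[0], src_lat[-1])
    # fractional index of each target center in the source lattice
    fx = (tx - src_lon[0]) / source_grid.resolution
    fy = (ty - src_lat[0]) / source_grid.resolution
    x0 = np.clip(np.floor(fx).astype(int), 0, source_grid.nx - 2) if source_grid.nx > 1 else np.zeros(len(fx), int)
    y0 = np.clip(np.floor(fy).astype(int), 0, source_grid.ny - 2) if source_grid.ny > 1 else np.zeros(len(fy), int)
    wx = fx - x0 if source_grid.nx > 1 else np.zeros(len(fx))
    wy = fy - y0 if source_grid.ny > 1 else np.zeros(len(fy))
    x1 = np.minimum(x0 + 1, source_grid.nx - 1)
    y1 = np.minimum(y0 + 1, source_grid.ny - 1)
    WX, WY = np.meshgrid(wx, wy)
    X0, Y0 = np.meshgrid(x0, y0)
    X1, Y1 = np.meshgrid(x1, y1)
    return (
        values[Y0, X0] * (1 - WX) * (1 - WY)
        + values[Y0, X1] * WX * (1 - WY)
        + values[Y1, X0] * (1 - WX) * WY
        + values[Y1, X1] * WX * WY
    )


def seasonal_summary(
    monthly_stack: RasterStack, months: list[str], statistic: str = "mean"
) -> np.ndarray:
    """Per-cell summary over the selected monthly layers.

    ``statistic`` is one of ``mean``, ``min``, ``max`` — the long-term
    seasonal climatologies (e.g. coldest-winter or hottest-summer fields)
    conventionally fed to intertidal niche models.
    """
    if not months:
        raise ValueError("empty month set")
    missing = [m for m in months if m not in monthly_stack]
    if missing:
        raise KeyError(f"months missing from stack: {missing}")
    cube = np.stack([monthly_stack[m] for m in months])
    reducers = {"mean": np.nanmean, "min": np.nanmin, "max": np.nanmax}
    if statistic not in reducers:
        raise ValueError(f"statistic must be one of {sorted(reducers)}")
    return reducers[statistic](cube, axis=0)


def spearman_screen(
    stack: RasterStack, mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Pairwise Spearman rank correlation of predictors across cells.

    NaN cells are excluded pairwise. Constant predictors have undefined
    correlation; they are logged and assigned R = 0 against everything
    (treated as incompatible with nothing).
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least two predictors")
    cols = {}
    for n in names:
        v = stack[n].ravel()
        if mask is not None:
            v = v[np.asarray(mask).ravel()]
        cols[n] = v
    if len(next(iter(cols.values()))) < 3:
        raise ValueError("need at least three cells")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    constants = {
        n for n, v in cols.items() if np.nanstd(v) == 0 or np.isnan(v).all()
    }
    for c in constants:
        warnings.warn(f"predictor {c!r} is constant; correlation undefined, set to 0")
    for a, b in itertools.combinations(names, 2):
        if a in constants or b in constants:
            r = 0.0
        else:
            ok = np.isfinite(cols[a]) & np.isfinite(cols[b])
            r = stats.spearmanr(cols[a][ok], cols[b][ok]).statistic
        out.loc[a, b] = out.loc[b, a] = r
    return out


def enumerate_combos(
    matrix: pd.DataFrame, min_size: int = 1, max_size: int = 4
) -> list[tuple[str, ...]]:
    """All predictor combinations whose pairwise |R| < 0.7, in lexicographic
    order, exhaustively for sizes ``min_size``..``max_size``."""
    names = sorted(matrix.columns)
    if not 1 <= min_size <= max_size <= len(names):
        raise ValueError("invalid size bounds")
    combos = []
    for size in range(min_size, max_size + 1):
        for combo in itertools.combinations(names, size):
            if all(
                abs(matrix.loc[a, b]) < 0.7
                for a, b in itertools.combinations(combo, 2)
            ):
                combos.append(combo)
    return combos
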