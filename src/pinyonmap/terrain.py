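"""Terrain derivatives: slope, aspect, ruggedness (TRI), vector ruggedness (VRM).

All kernels operate on the 3x3 neighbourhood (VRM window is configurable)
with edge replication at the borders, so outputs keep the DEM's shape. An
optional nodata border policy masks the outermost ring instead.

Conventions
-----------
slope   degrees, Horn 3x3 finite differences, in [0, 90)
aspect  degrees clockwise from north of the downslope direction, in
        [0, 360); flat cells (zero gradient) are nodata
TRI     Riley's square root of summed squared centre-neighbour elevation
        differences by default; the plain sum and the mean of absolute
        differences (the GDAL/QGIS convention) are available as variants
VRM     1 - |R|/n, dispersion of unit surface normals over the window;
        0 on any plane, approaching 1 for maximally rough terrain
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .grid import CONTINUOUS, Grid

TRI_VARIANTS = ("riley_sqrt_sum_squares", "sum_abs", "mean_abs")


@dataclass
class TerrainSet:
    """Bundle of the four terrain grids derived from one DEM."""

    slope: Grid
    aspect: Grid
    tri: Grid
    vrm: Grid


def _check_dem(dem: Grid, min_size: int = 3) -> None:
    rows, cols = dem.shape
    if rows < min_size or cols < min_size:
        raise ConfigError(f"DEM must be at least {min_size}x{min_size}, got {dem.shape}")
    if not np.isfinite(dem.cell_size) or dem.cell_size <= 0:
        raise ConfigError(f"DEM cell size must be positive, got {dem.cell_size}")


def _padded(dem: Grid) -> np.ndarray:
    return np.pad(dem.values.astype(float), 1, mode="edge")


def _apply_border(mask: np.ndarray, border: str) -> np.ndarray:
    if border == "nodata":
        mask = mask.copy()
        mask[0, :] = mask[-1, :] = True
        mask[:, 0] = mask[:, -1] = True
    return mask


def horn_gradients(dem: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3x3 gradients (dz/dx eastward, dz/dy northward), edge replicated.

    Rows increase southward, so the northward derivative is the negated
    row-wise difference.
    """
    z = _padded(dem)
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    cs = dem.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)
    return dzdx, dzdy


def compute_slope_aspect(dem: Grid, border: str = "edge") -> tuple[Grid, Grid]:
    """Slope (degrees) and aspect (degrees clockwise from north, flat=nodata)."""
    _check_dem(dem)
    dzdx, dzdy = horn_gradients(dem)
    grad = np.hypot(dzdx, dzdy)
    slope_vals = np.degrees(np.arctan(grad))
    flat = grad == 0
    # Downslope direction is -grad; azimuth measured from north, clockwise.
    aspect_vals = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect_vals = np.where(flat, 0.0, aspect_vals)
    base = _apply_border(dem.nodata_mask, border)
    slope = Grid(values=slope_vals, cell_size=dem.cell_size,
                 nodata_mask=base, kind=CONTINUOUS)
    aspect = Grid(values=aspect_vals, cell_size=dem.cell_size,
                  nodata_mask=base | flat, kind=CONTINUOUS)
    return slope, aspect


def compute_tri(dem: Grid, variant: str = "riley_sqrt_sum_squares",
                border: str = "edge") -> Grid:
    """Terrain ruggedness index over the 8-neighbourhood.

    Nodata neighbours are excluded; for ``mean_abs`` the divisor is the
    number of valid neighbours.
    """
    _check_dem(dem)
    if variant not in TRI_VARIANTS:
        raise ConfigError(f"unknown TRI variant {variant!r}; choose from {TRI_VARIANTS}")
    z = _padded(dem)
    valid = np.pad(~dem.nodata_mask, 1, mode="edge").astype(float)
    centre = z[1:-1, 1:-1]
    sq = np.zeros(dem.shape)
    ab = np.zeros(dem.shape)
    nvalid = np.zeros(dem.shape)
    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    for di, dj in offsets:
        nb = z[1 + di:z.shape[0] - 1 + di, 1 + dj:z.shape[1] - 1 + dj]
        ok = valid[1 + di:valid.shape[0] - 1 + di, 1 + dj:valid.shape[1] - 1 + dj]
        diff = (nb - centre) * ok
        sq += diff**2
        ab += np.abs(diff)
        nvalid += ok
    if variant == "riley_sqrt_sum_squares":
        vals = np.sqrt(sq)
    elif variant == "sum_abs":
        vals = ab
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(nvalid > 0, ab / np.maximum(nvalid, 1), 0.0)
    mask = _apply_border(dem.nodata_mask, border)
    return Grid(values=vals, cell_size=dem.cell_size, nodata_mask=mask, kind=CONTINUOUS)


def surface_normals(dem: Grid) -> np.ndarray:
    """Per-cell unit surface normals, shape (rows, cols, 3).

    x = sin(slope)sin(aspect), y = sin(slope)cos(aspect), z = cos(slope);
    flat cells contribute the vertical normal (0, 0, 1).
    """
    slope, aspect = compute_slope_aspect(dem)
    s = np.radians(slope.values)
    a = np.radians(np.where(aspect.nodata_mask, 0.0, aspect.values))
    sin_s = np.sin(s)
    return np.stack([sin_s * np.sin(a), sin_s * np.cos(a), np.cos(s)], axis=-1)


def compute_vrm(dem: Grid, window: int = 3, border: str = "edge") -> Grid:
    """Vector ruggedness measure: 1 - |resultant| / n over a square window."""
    if window < 3 or window % 2 == 0:
        raise ConfigError(f"VRM window must be an odd integer >= 3, got {window}")
    _check_dem(dem, min_size=window)
    normals = surface_normals(dem)
    n = window * window
    sums = np.stack([
        ndimage.uniform_filter(normals[..., k], size=window, mode="nearest") * n
        for k in range(3)
    ], axis=-1)
    resultant = np.linalg.norm(sums, axis=-1)
    vals = np.clip(1.0 - resultant / n, 0.0, 1.0)
    mask = _apply_border(dem.nodata_mask, border)
    return Grid(values=vals, cell_size=dem.cell_size, nodata_mask=mask, kind=CONTINUOUS)


def compute_terrain(dem: Grid, tri_variant: str = "riley_sqrt_sum_squares",
                    vrm_window: int = 3, border: str = "edge") -> TerrainSet:
    slope, aspect = compute_slope_aspect(dem, border=border)
    return TerrainSet(
        slope=slope,
        aspect=aspect,
        tri=compute_tri(dem, variant=tri_variant, border=border),
        vrm=compute_vrm(dem, window=vrm_window, border=border),
    )
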