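"""Raster container and plain-text raster I/O.

A :class:`Grid` is the common carrier for every 2-D layer in the pipeline:
elevation, reflectance bands, vegetation indices, terrain metrics, climate
surfaces and categorical cover maps. Grids are written as ESRI ASCII rasters
(``.asc``), a text format readable by GDAL and QGIS, with a placeholder
origin — the scenes are synthetic and carry no real-world georeference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError

NODATA_VALUE = -9999.0

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class Grid:
    """A 2-D raster layer with cell size, nodata mask and semantics.

    Parameters
    ----------
    values : ndarray of shape (rows, cols)
        Cell values. Categorical grids hold integer class codes.
    cell_size : float
        Cell edge length in metres.
    nodata_mask : ndarray of bool, optional
        True where the cell carries no value. Defaults to all-valid.
    kind : {"continuous", "categorical"}
    """

    values: np.ndarray
    cell_size: float = 10.0
    nodata_mask: np.ndarray | None = None
    kind: str = CONTINUOUS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ConfigError(f"grid values must be 2-D, got ndim={self.values.ndim}")
        if self.cell_size <= 0:
            raise ConfigError(f"cell_size must be positive, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ConfigError(
                f"nodata mask shape {self.nodata_mask.shape} != values shape {self.values.shape}"
            )
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ConfigError(f"unknown grid kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            valid = self.values[~self.nodata_mask]
            if valid.size and not np.all(np.equal(np.mod(valid, 1), 0)):
                raise DataError("categorical grid contains non-integer class codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def like(self, values: np.ndarray, kind: str | None = None,
             nodata_mask: np.ndarray | None = None) -> "Grid":
        """New grid sharing this grid's cell size."""
        return Grid(
            values=values,
            cell_size=self.cell_size,
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
            kind=self.kind if kind is None else kind,
        )


def write_ascii_grid(grid: Grid, path: str | Path) -> Path:
    """Write a grid as an ESRI ASCII raster (text)."""
    path = Path(path)
    vals = np.where(grid.nodata_mask, NODATA_VALUE, grid.values.astype(float))
    rows, cols = grid.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {NODATA_VALUE}\n"
    )
    fmt = "%d" if grid.kind == CATEGORICAL else "%.6f"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    return path


def read_ascii_grid(path: str | Path, kind: str = CONTINUOUS) -> Grid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    vals = np.loadtxt(lines[n_header:])
    vals = np.atleast_2d(vals)
    nodata = meta.get("nodata_value", NODATA_VALUE)
    mask = vals == nodata
    if kind == CATEGORICAL:
        vals = np.where(mask, 0, vals).astype(int)
    return Grid(values=vals, cell_size=meta.get("cellsize", 1.0),
                nodata_mask=mask, kind=kind)
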