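"""Band bookkeeping: resampling, NDVI, and the 11-feature scene stack."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DataError
from .grid import CONTINUOUS, Grid, read_ascii_grid, write_ascii_grid

#: Canonical band order of the ten-band stack; NDVI is appended last so a
#: trained model's feature order is portable across runs.
BAND_ORDER = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")
NDVI_NAME = "NDVI"


@dataclass
class SceneStack:
    """Ordered multiband stack on a common grid, NDVI appended as feature 11."""

    bands: dict[str, Grid]
    ndvi: Grid | None = None

    def __post_init__(self) -> None:
        shapes = {name: g.shape for name, g in self.bands.items()}
        if self.ndvi is not None:
            shapes[NDVI_NAME] = self.ndvi.shape
        if len(set(shapes.values())) > 1:
            raise ConfigError(f"stack members disagree in shape: {shapes}")

    @property
    def feature_names(self) -> tuple[str, ...]:
        names = tuple(self.bands.keys())
        return names + (NDVI_NAME,) if self.ndvi is not None else names

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def n_features(self) -> int:
        return len(self.bands) + (1 if self.ndvi is not None else 0)

    def grids(self) -> list[Grid]:
        out = list(self.bands.values())
        if self.ndvi is not None:
            out.append(self.ndvi)
        return out

    def nodata_any(self) -> np.ndarray:
        """Cells where any feature is nodata."""
        mask = np.zeros(self.shape, dtype=bool)
        for g in self.grids():
            mask |= g.nodata_mask
        return mask

    def as_matrix(self) -> np.ndarray:
        """(rows*cols, n_features) feature matrix in row-major cell order."""
        return np.stack([g.values.ravel() for g in self.grids()], axis=1)

    def features_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.stack([g.values[rows, cols] for g in self.grids()], axis=1)


def resample_to_fine(coarse: Grid, factor: int, method: str = "bilinear") -> Grid:
    """Upsample a grid by an integer factor.

    ``nearest`` replicates each source cell into a ``factor x factor``
    block; ``bilinear`` interpolates between source cell centres with edge
    clamping. Nodata propagates to every output cell whose interpolation
    support touches a nodata source cell.
    """
    if factor < 1 or int(factor) != factor:
        raise ConfigError(f"resampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if method not in ("nearest", "bilinear"):
        raise ConfigError(f"unknown resampling method {method!r}")
    if factor == 1:
        return Grid(values=coarse.values.copy(), cell_size=coarse.cell_size,
                    nodata_mask=coarse.nodata_mask.copy(), kind=coarse.kind)
    if method == "nearest":
        vals = np.repeat(np.repeat(coarse.values, factor, axis=0), factor, axis=1)
        mask = np.repeat(np.repeat(coarse.nodata_mask, factor, axis=0), factor, axis=1)
    else:
        rows, cols = coarse.shape
        out_r = (np.arange(rows * factor) + 0.5) / factor - 0.5
        out_c = (np.arange(cols * factor) + 0.5) / factor - 0.5
        rr, cc = np.meshgrid(out_r, out_c, indexing="ij")
        coords = np.stack([rr.ravel(), cc.ravel()])
        vals = ndimage.map_coordinates(
            coarse.values.astype(float), coords, order=1, mode="nearest"
        ).reshape(rows * factor, cols * factor)
        touched = ndimage.map_coordinates(
            coarse.nodata_mask.astype(float), coords, order=1, mode="nearest"
        ).reshape(rows * factor, cols * factor)
        mask = touched > 1e-12
    return Grid(values=vals, cell_size=coarse.cell_size / factor,
                nodata_mask=mask, kind=coarse.kind)


def compute_ndvi(nir: Grid, red: Grid) -> Grid:
    """Normalized difference vegetation index, (NIR - R) / (NIR + R).

    Cells where the denominator is zero become nodata rather than zero:
    a blank cell carries no vegetation signal. Nodata in either input
    propagates.
    """
    if nir.shape != red.shape:
        raise DataError(f"NIR shape {nir.shape} != red shape {red.shape}")
    denom = nir.values + red.values
    mask = nir.nodata_mask | red.nodata_mask | (denom == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(mask, 0.0, (nir.values - red.values) / np.where(denom == 0, 1.0, denom))
    return Grid(values=vals, cell_size=nir.cell_size, nodata_mask=mask, kind=CONTINUOUS)


def stack_scene(bands: dict[str, Grid], ndvi: Grid | None = None) -> SceneStack:
    """Assemble the canonical stack: B2..B12 in fixed order, NDVI last."""
    missing = [b for b in BAND_ORDER if b not in bands]
    if missing:
        raise ConfigError(f"stack missing required bands: {missing}")
    ordered = {b: bands[b] for b in BAND_ORDER}
    return SceneStack(bands=ordered, ndvi=ndvi)


def build_stack(bands: dict[str, Grid]) -> SceneStack:
    """Stack bands and derive NDVI from NIR (B8) and red (B4)."""
    ndvi = compute_ndvi(bands["B8"], bands["B4"])
    return stack_scene(bands, ndvi)


def write_stack(stack: SceneStack, out_dir: str | Path) -> Path:
    """Serialize a stack as one ASCII raster per band plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    order = []
    for name, g in zip(stack.feature_names, stack.grids()):
        write_ascii_grid(g, out_dir / f"{name}.asc")
        order.append(name)
    manifest = out_dir / "stack.json"
    manifest.write_text(json.dumps({"band_order": order}, indent=1))
    return manifest


def read_stack(out_dir: str | Path) -> SceneStack:
    out_dir = Path(out_dir)
    order = json.loads((out_dir / "stack.json").read_text())["band_order"]
    grids = {name: read_ascii_grid(out_dir / f"{name}.asc") for name in order}
    ndvi = grids.pop(NDVI_NAME, None)
    return stack_scene(grids, ndvi)
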