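"""Seeded synthetic desert-mountain landscapes.

Generates the full input set the mapping pipeline needs — a DEM, coarse
climate covariate surfaces, a four-class cover truth map (pinyon pine,
scrub, chaparral, no-apparent-vegetation), ten reflectance bands and a
stratified reference sample — with a statistical structure that mimics an
isolated semi-arid sierra: elevation spanning 280–1,662 m, xerophilous
scrub in the lowlands, chaparral above ~800 m, and pine occurring above a
~1,010 m floor with a probability driven by terrain ruggedness (TRI, VRM)
and warm-month temperature (MTWM) through a known logistic model. Class
reflectances are tuned so the normalized difference vegetation index
separates the classes the way sparse desert vegetation does: scrub around
0.10–0.15, chaparral 0.24–0.28, pine 0.30–0.41.

Every output is a pure function of ``(config, seed)``; per-operation
random streams are derived from the scene seed so stages can be rerun in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, DataError, SamplingError
from .grid import CATEGORICAL, CONTINUOUS, Grid

BAND_NAMES = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

# Reflectance means per class for the ten bands above. Only the red (B4)
# and NIR (B8/B8A) pair is strongly class-separating; the remaining bands
# differ mildly, mimicking the redundancy of real multispectral stacks.
# The B4/B8 pairs put class NDVI centres at 0.355 (pine), 0.26 (chaparral),
# 0.125 (scrub) and ~0.03 (bare ground).
DEFAULT_CLASS_SPECTRA: dict[str, tuple[float, ...]] = {
    #          B2     B3     B4     B5     B6     B7     B8     B8A    B11    B12
    "pine":      (0.040, 0.062, 0.1428, 0.150, 0.200, 0.250, 0.300, 0.305, 0.190, 0.120),
    "scrub":     (0.052, 0.075, 0.1944, 0.200, 0.215, 0.235, 0.250, 0.252, 0.270, 0.210),
    "chaparral": (0.046, 0.070, 0.1644, 0.180, 0.210, 0.245, 0.280, 0.283, 0.230, 0.165),
    "nap":       (0.060, 0.085, 0.2261, 0.230, 0.235, 0.238, 0.240, 0.241, 0.320, 0.270),
}

DEFAULT_NDVI_TARGETS: dict[str, tuple[float, float]] = {
    "pine": (0.30, 0.41),
    "chaparral": (0.24, 0.28),
    "scrub": (0.10, 0.15),
    "nap": (-0.05, 0.10),
}

# Logistic model generating pine presence on eligible (high-elevation)
# cells: intercept, ruggedness (TRI, metres), warm-month mean temperature
# (MTWM, deg C), vector ruggedness (VRM, unitless).
DEFAULT_TRUTH_MODEL: dict[str, float] = {
    "intercept": 25.351,
    "beta_TRI": 0.178,
    "beta_MTWM": -1.159,
    "beta_VRM": 28.476,
}

DEFAULT_SAMPLES_PER_CLASS: dict[str, int] = {
    "pine": 536, "scrub": 764, "chaparral": 405, "nap": 438,
}

# Stream tags so each generator op draws from an independent child stream.
_STREAMS = {"dem": 11, "climate": 23, "truth": 37, "spectra": 53, "sample": 71}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    The defaults describe the study conditions the pipeline is meant to
    emulate: a 120x120 grid of 10 m cells spanning 280-1662 m elevation,
    four cover classes with a stratified reference sample of 536/764/405/438
    points, and pine presence following the default logistic truth model.
    """

    grid_rows: int = 288
    grid_cols: int = 288
    cell_size: float = 10.0
    elevation_range: tuple[float, float] = (280.0, 1662.0)
    class_names: tuple[str, ...] = ("pine", "scrub", "chaparral", "nap")
    class_spectra: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SPECTRA))
    spectral_noise_sd: float = 0.007
    brightness_sd: float = 0.35
    ndvi_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NDVI_TARGETS))
    truth_model: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_MODEL))
    pine_elevation_floor: float = 1010.0
    mtwm_range: tuple[float, float] = (23.5, 25.2)
    mtwm_noise_sd: float = 0.05
    climate_block_cells: int = 8
    samples_per_class: int | Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES_PER_CLASS))
    n_bumps: int = 14
    bump_sigma_cells: tuple[float, float] = (25.0, 70.0)
    dem_noise_rel: float = 0.0015
    elevation_dither_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ConfigError("grid dimensions must be positive")
        lo, hi = self.elevation_range
        if not lo < hi:
            raise ConfigError(f"elevation_range must satisfy min < max, got {self.elevation_range}")
        if self.climate_block_cells < 1:
            raise ConfigError("climate_block_cells must be >= 1")
        for name in self.class_names:
            if name not in self.class_spectra:
                raise ConfigError(f"class {name!r} has no spectra")
            if len(self.class_spectra[name]) != len(BAND_NAMES):
                raise ConfigError(f"class {name!r} spectra must cover all {len(BAND_NAMES)} bands")
        for n in self.per_class_counts().values():
            if n < 1:
                raise ConfigError("samples_per_class must be >= 1")

    def per_class_counts(self) -> dict[str, int]:
        if isinstance(self.samples_per_class, Mapping):
            return {c: int(self.samples_per_class.get(c, 400)) for c in self.class_names}
        return {c: int(self.samples_per_class) for c in self.class_names}

    def class_code(self, name: str) -> int:
        return self.class_names.index(name)

    def with_seed(self, seed: int) -> "SceneConfig":
        return replace(self, seed=int(seed))


def generate_dem(config: SceneConfig) -> Grid:
    """Smooth correlated elevation surface rescaled exactly to the configured range.

    A superposition of seeded Gaussian bumps plus low-amplitude white noise,
    affinely rescaled so the grid minimum and maximum hit
    ``config.elevation_range`` exactly.
    """
    rng = _rng(config.seed, "dem")
    rows, cols = config.grid_rows, config.grid_cols
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    surface = np.zeros((rows, cols))
    for _ in range(config.n_bumps):
        cy = rng.uniform(0, rows)
        cx = rng.uniform(0, cols)
        sig = rng.uniform(*config.bump_sigma_cells)
        amp = rng.uniform(0.4, 1.0)
        surface += amp * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sig**2))
    span = surface.max() - surface.min()
    if span == 0:  # pathological config (zero bumps)
        span = 1.0
    surface = (surface - surface.min()) / span
    surface += rng.normal(0.0, config.dem_noise_rel, size=surface.shape)
    lo, hi = config.elevation_range
    surface = (surface - surface.min()) / (surface.max() - surface.min())
    values = lo + surface * (hi - lo)
    return Grid(values=values, cell_size=config.cell_size, kind=CONTINUOUS)


def _block_reduce_mean(values: np.ndarray, block: int) -> np.ndarray:
    """Mean over block x block tiles (edge tiles may be smaller)."""
    rows, cols = values.shape
    rb = -(-rows // block)
    cb = -(-cols // block)
    out = np.empty((rb, cb))
    for i in range(rb):
        for j in range(cb):
            out[i, j] = values[i * block:(i + 1) * block, j * block:(j + 1) * block].mean()
    return out


def _block_expand(blocks: np.ndarray, block: int, shape: tuple[int, int]) -> np.ndarray:
    full = np.repeat(np.repeat(blocks, block, axis=0), block, axis=1)
    return full[: shape[0], : shape[1]]


def generate_covariates(dem: Grid, config: SceneConfig) -> dict[str, Grid]:
    """Coarse climate surfaces plus uninformative screening covariates.

    MTWM (mean temperature of the warmest month) is a lapse-rate transform
    of block-mean elevation — higher terrain is cooler — held constant
    within ``climate_block_cells``-sized blocks to mimic the resolution
    mismatch between an ~800 m climate product and a 10 m scene, with
    seeded block-level noise, clipped into ``mtwm_range``. MMAX (maximum
    temperature of the warmest month) is a nearly collinear shift of MTWM,
    giving the collinearity-pruning stage a realistic victim. NOISE1 and
    NOISE2 are pure white noise for type-I screening checks.
    """
    rng = _rng(config.seed, "climate")
    block = config.climate_block_cells
    t_lo, t_hi = config.mtwm_range
    elev_blocks = _block_reduce_mean(dem.values, block)
    e_lo, e_hi = config.elevation_range
    frac = (elev_blocks - e_lo) / (e_hi - e_lo)
    mtwm_blocks = t_hi - frac * (t_hi - t_lo)
    if config.mtwm_noise_sd > 0:
        mtwm_blocks = mtwm_blocks + rng.normal(0, config.mtwm_noise_sd, mtwm_blocks.shape)
    mtwm_blocks = np.clip(mtwm_blocks, t_lo, t_hi)
    mmax_blocks = np.clip(mtwm_blocks + 9.58 + rng.normal(0, 0.03, mtwm_blocks.shape),
                          t_lo + 9.0, t_hi + 10.0)
    shape = dem.shape
    out = {
        "MTWM": dem.like(_block_expand(mtwm_blocks, block, shape)),
        "MMAX": dem.like(_block_expand(mmax_blocks, block, shape)),
        "NOISE1": dem.like(rng.normal(0, 1, shape)),
        "NOISE2": dem.like(rng.normal(0, 1, shape)),
    }
    return out


def generate_cover_truth(dem: Grid, env: Mapping[str, Grid], config: SceneConfig) -> Grid:
    """Categorical cover truth: logistic pine above the elevation floor,
    elevation-banded scrub/chaparral/bare elsewhere.

    ``env`` must provide TRI, VRM and MTWM grids. On cells at or above
    ``pine_elevation_floor`` pine presence is Bernoulli with probability
    ``expit(intercept + beta_TRI*TRI + beta_MTWM*MTWM + beta_VRM*VRM)``.
    Remaining cells are banded on dithered elevation: low cells are mostly
    bare ground (no apparent vegetation), mid cells scrub, cells above
    ~800 m chaparral.
    """
    for key in ("TRI", "VRM", "MTWM"):
        if key not in env:
            raise ConfigError(f"cover truth needs env grid {key!r}")
    tm = config.truth_model
    for key in ("intercept", "beta_TRI", "beta_MTWM", "beta_VRM"):
        if key not in tm:
            raise ConfigError(f"truth_model missing coefficient {key!r}")
    rng = _rng(config.seed, "truth")
    elev = dem.values
    lp = (tm["intercept"]
          + tm["beta_TRI"] * env["TRI"].values
          + tm["beta_MTWM"] * env["MTWM"].values
          + tm["beta_VRM"] * env["VRM"].values)
    p_pine = expit(lp)
    eligible = elev >= config.pine_elevation_floor
    pine = eligible & (rng.uniform(size=elev.shape) < p_pine)

    dithered = elev + rng.normal(0, config.elevation_dither_sd, elev.shape)
    codes = np.full(elev.shape, config.class_code("chaparral"), dtype=int)
    codes[dithered < 800.0] = config.class_code("scrub")
    low = dithered < 560.0
    nap_draw = rng.uniform(size=elev.shape) < 0.75
    codes[low & nap_draw] = config.class_code("nap")
    codes[pine] = config.class_code("pine")

    grid = Grid(values=codes, cell_size=dem.cell_size,
                nodata_mask=dem.nodata_mask.copy(), kind=CATEGORICAL)
    present = set(np.unique(codes[~grid.nodata_mask]).tolist())
    missing = [c for i, c in enumerate(config.class_names) if i not in present]
    if missing:
        raise DataError(f"generated scene lacks classes: {missing}; "
                        "enlarge the grid or adjust elevation structure")
    return grid


def pine_presence_probability(env: Mapping[str, Grid], config: SceneConfig) -> np.ndarray:
    """Configured per-cell pine probability (the generator's own truth surface)."""
    tm = config.truth_model
    return expit(tm["intercept"]
                 + tm["beta_TRI"] * env["TRI"].values
                 + tm["beta_MTWM"] * env["MTWM"].values
                 + tm["beta_VRM"] * env["VRM"].values)


def generate_spectra(cover: Grid, config: SceneConfig) -> dict[str, Grid]:
    """Per-class mean reflectance with illumination and sensor noise, clipped to [0, 1].

    Each cell carries a lognormal multiplicative brightness factor shared
    by all bands — the stand-in for topographic illumination, which scales
    reflectance jointly across bands and therefore cancels in band ratios
    such as NDVI — plus independent additive Gaussian noise per band.
    """
    rng = _rng(config.seed, "spectra")
    codes = cover.values
    present = np.unique(codes[~cover.nodata_mask])
    for code in present:
        if code < 0 or code >= len(config.class_names):
            raise ConfigError(f"cover contains class code {code} without spectra")
    means = np.array([config.class_spectra[c] for c in config.class_names])  # (q, nbands)
    brightness = np.exp(rng.normal(0.0, config.brightness_sd, codes.shape))
    out: dict[str, Grid] = {}
    for b, band in enumerate(BAND_NAMES):
        noise = rng.normal(0, config.spectral_noise_sd, codes.shape)
        noisy = brightness * (means[codes, b] + noise)
        out[band] = Grid(values=np.clip(noisy, 0.0, 1.0), cell_size=cover.cell_size,
                         nodata_mask=cover.nodata_mask.copy(), kind=CONTINUOUS)
    return out


def sample_reference(cover: Grid, config: SceneConfig,
                     counts: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Stratified random reference sample, without replacement, seeded.

    Returns a table with columns ``row``, ``col``, ``true_class`` (class
    name of the sampled cell in ``cover``). Raises :class:`SamplingError`
    naming the class if a stratum has fewer cells than requested.
    """
    rng = _rng(config.seed, "sample")
    counts = dict(counts) if counts is not None else config.per_class_counts()
    rows_out: list[pd.DataFrame] = []
    for name in config.class_names:
        want = int(counts[name])
        code = config.class_code(name)
        rr, cc = np.nonzero((cover.values == code) & ~cover.nodata_mask)
        if rr.size < want:
            raise SamplingError(
                f"class {name!r} has only {rr.size} cells, cannot sample {want}")
        pick = rng.choice(rr.size, size=want, replace=False)
        rows_out.append(pd.DataFrame({
            "row": rr[pick], "col": cc[pick],
            "true_class": name,
        }))
    table = pd.concat(rows_out, ignore_index=True)
    return table


def generate_scene(config: SceneConfig) -> dict:
    """Convenience end-to-end generation: DEM, terrain, climate, truth, bands.

    Returns a dict with keys ``dem``, ``terrain`` (slope/aspect/TRI/VRM
    grids), ``covariates``, ``cover``, ``bands``, ``config``.
    """
    from .terrain import compute_slope_aspect, compute_tri, compute_vrm

    dem = generate_dem(config)
    slope, aspect = compute_slope_aspect(dem)
    tri = compute_tri(dem)
    vrm = compute_vrm(dem)
    covariates = generate_covariates(dem, config)
    env = {"TRI": tri, "VRM": vrm, "MTWM": covariates["MTWM"]}
    cover = generate_cover_truth(dem, env, config)
    bands = generate_spectra(cover, config)
    return {
        "dem": dem,
        "terrain": {"slope": slope, "aspect": aspect, "TRI": tri, "VRM": vrm},
        "covariates": covariates,
        "cover": cover,
        "bands": bands,
        "config": config,
    }
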