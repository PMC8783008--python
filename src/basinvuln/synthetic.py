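"""Self-contained synthetic worlds for the vulnerability pipeline.

A synthetic world emulates the statistical structure of the analysis
inputs: non-negative, skewed withdrawal and streamflow with W/Q spanning
[0, >1]; signed, spatially correlated total-water-storage trends; adaptive
capacity in [0,1]; heavy-tailed ecological-sensitivity fields (one with
partial coverage); extensive socio-economic fields; a contiguous basin
tessellation; nation polygons overlapping basins; and optional planted
hotspots with known ground truth for recovery tests. Everything is
reproducible from a single integer seed.

Basins are grown by seeded region growing (multi-source shortest paths with
random edge weights), which guarantees contiguity and yields compact,
irregular shapes reminiscent of drainage basins without any hydrological
routing. Spatially correlated fields are Gaussian random fields
approximated by kernel-smoothed white noise.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import BasinScheme, GeoGrid, cell_area_grid, grid_coords


class InvalidSpecError(ValueError):
    """Raised when a synthetic-world specification is inconsistent."""


# rng sub-stream ids (combined with the master seed)
_STREAM_BASINS = 1
_STREAM_NATIONS = 2
_STREAM_SCORES = 3
_STREAM_WETLANDS = 4
_STREAM_FIELDS = 10  # + field index


@dataclass(frozen=True)
class FieldSpec:
    """Marginal distribution and spatial structure of one gridded input.

    ``dist`` is 'lognormal' (loc = median > 0, scale = sigma of log),
    'gaussian' (loc = mean, scale = sd), or 'beta' (loc, scale = shape
    parameters a, b; support [0,1]). ``corr_len`` is the spatial correlation
    length in cells (0 = independent cells); ``coverage`` is the fraction of
    cells with valid data.
    """

    dist: str
    loc: float
    scale: float
    corr_len: float = 0.0
    coverage: float = 1.0
    units: str = ""

    def validate(self, name: str) -> None:
        if self.dist not in ("lognormal", "gaussian", "beta"):
            raise InvalidSpecError(f"{name}: unknown distribution {self.dist!r}")
        if self.scale < 0:
            raise InvalidSpecError(f"{name}: scale must be >= 0")
        if self.dist == "lognormal" and self.loc <= 0:
            raise InvalidSpecError(f"{name}: lognormal median must be > 0")
        if self.dist == "beta" and (self.loc <= 0 or self.scale <= 0):
            raise InvalidSpecError(f"{name}: beta shapes must be > 0")
        if self.corr_len < 0:
            raise InvalidSpecError(f"{name}: corr_len must be >= 0")
        if not 0 < self.coverage <= 1:
            raise InvalidSpecError(f"{name}: coverage must be in (0, 1]")


@dataclass(frozen=True)
class PlantedHotspot:
    """Ground-truth manipulation of one basin to force joint vulnerability.

    The basin's cell stress ratios W/Q are floored at the global median
    ratio and then multiplied by ``stress_multiplier`` (by raising W), so a
    planted basin's stress exceeds the non-planted median by the multiplier
    regardless of where the basin started; the storage trend is shifted by
    ``trend_offset`` (mm/yr, negative = drying); adaptive capacity is capped
    at ``adaptability_ceiling``; both ecological fields are floored at the
    global quantile ``sensitivity_floor`` of their own distribution.
    """

    basin_id: int
    stress_multiplier: float = 5.0
    trend_offset: float = -30.0
    adaptability_ceiling: float = 0.2
    sensitivity_floor: float = 0.8


def default_field_params() -> dict[str, FieldSpec]:
    """Default marginals, loosely scaled to global 0.5-degree datasets.

    Streamflow ~ a few hundred mm/yr with order-of-magnitude spread;
    withdrawal a heavy-tailed fraction of it so the stress ratio W/Q centres
    near 0.1 and exceeds 1 in a small tail; storage trends are
    GRACE-magnitude (sd ~ 8 mm/yr) and spatially smooth; the head-decline
    proxy covers only part of the surface, as groundwater pumping does.
    """
    return {
        "withdrawal": FieldSpec("lognormal", 20.0, 1.5, 3.0, units="mm yr-1"),
        "streamflow": FieldSpec("lognormal", 200.0, 1.0, 3.0, units="mm yr-1"),
        "tws_trend": FieldSpec("gaussian", 0.0, 8.0, 4.0, units="mm yr-1"),
        "adaptive_capacity": FieldSpec("beta", 2.0, 2.0, 4.0, units="1"),
        "eco_flow_sensitivity": FieldSpec(
            "lognormal", 1.0, 1.2, 2.0, coverage=0.6, units="m"
        ),
        "veg_water_sensitivity": FieldSpec("lognormal", 1.0, 1.0, 2.0, units="1"),
        "population": FieldSpec("lognormal", 5e4, 1.5, 1.0, units="persons"),
        "crop_production": FieldSpec("lognormal", 1e5, 1.5, 1.0, units="kcal"),
        "gdp": FieldSpec("lognormal", 1e6, 2.0, 1.0, units="currency"),
        "species_richness": FieldSpec("lognormal", 100.0, 0.5, 3.0, units="species"),
    }


#: Fields perturbed by the uncertainty analysis (the analysis inputs).
ANALYSIS_FIELDS = (
    "withdrawal",
    "streamflow",
    "tws_trend",
    "adaptive_capacity",
    "eco_flow_sensitivity",
    "veg_water_sensitivity",
)
#: Extensive fields summed within basins for exposure accounting.
EXTENSIVE_FIELDS = ("population", "crop_production", "gdp")


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Everything needed to generate one reproducible synthetic world."""

    resolution: float = 0.5
    lat_extent: tuple[float, float] = (-20.0, 20.0)
    lon_extent: tuple[float, float] = (0.0, 50.0)
    n_basins: int = 200
    n_nations: int = 12
    n_wetlands: int = 300
    mask_rows_fraction: float = 0.05
    field_params: Mapping[str, FieldSpec] = field(default_factory=default_field_params)
    planted_hotspots: tuple[PlantedHotspot, ...] = ()
    earthquake_basins: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_hotspots", tuple(self.planted_hotspots))
        object.__setattr__(self, "earthquake_basins", tuple(self.earthquake_basins))
        object.__setattr__(self, "field_params", dict(self.field_params))

    def validate(self) -> None:
        if self.n_basins < 1:
            raise InvalidSpecError("n_basins must be >= 1")
        if self.n_nations < 1:
            raise InvalidSpecError("n_nations must be >= 1")
        if not 0 <= self.mask_rows_fraction < 1:
            raise InvalidSpecError("mask_rows_fraction must be in [0, 1)")
        for name, fs in self.field_params.items():
            fs.validate(name)
        lat, lon = self.grid()  # raises if resolution does not divide extent
        unmasked = (lat.size - self._n_masked_rows(lat.size)) * lon.size
        if self.n_basins > unmasked:
            raise InvalidSpecError(
                f"n_basins={self.n_basins} exceeds {unmasked} unmasked cells"
            )

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        return grid_coords(self.lat_extent, self.lon_extent, self.resolution)

    def _n_masked_rows(self, nlat: int) -> int:
        return int(round(self.mask_rows_fraction * nlat))

    def cell_mask(self) -> np.ndarray:
        """Boolean grid, True where cells are masked (no basin, no data)."""
        lat, lon = self.grid()
        mask = np.zeros((lat.size, lon.size), dtype=bool)
        mask[: self._n_masked_rows(lat.size), :] = True
        return mask

    def replace(self, **kwargs) -> "SyntheticWorldSpec":
        return replace(self, **kwargs)


def _region_grow(
    valid: np.ndarray, n_regions: int, rng: np.random.Generator
) -> np.ndarray:
    """Partition the valid cells of a grid into contiguous regions.

    Multi-source Dijkstra from random seed cells with exponentially
    distributed random edge weights: every cell joins the region of its
    cheapest-path seed, so regions are connected, compact, and irregular.
    Returns an int raster with region ids 1..n_regions (0 where invalid).
    """
    nlat, nlon = valid.shape
    flat_valid = np.flatnonzero(valid.ravel())
    if n_regions > flat_valid.size:
        raise InvalidSpecError("more regions requested than valid cells")
    seeds = rng.choice(flat_valid, size=n_regions, replace=False)
    labels = np.zeros(nlat * nlon, dtype=np.int32)
    heap: list[tuple[float, int, int]] = []
    for k, cell in enumerate(sorted(seeds.tolist())):
        heapq.heappush(heap, (0.0, int(cell), k + 1))
    valid_flat = valid.ravel()
    while heap:
        cost, cell, region = heapq.heappop(heap)
        if labels[cell]:
            continue
        labels[cell] = region
        i, j = divmod(cell, nlon)
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < nlat and 0 <= nj < nlon:
                ncell = ni * nlon + nj
                if valid_flat[ncell] and not labels[ncell]:
                    heapq.heappush(
                        heap, (cost + rng.exponential(), ncell, region)
                    )
    return labels.reshape(nlat, nlon)


def _correlated_standard_field(
    rng: np.random.Generator, shape: tuple[int, int], corr_len: float
) -> np.ndarray:
    """Zero-mean unit-variance field with Gaussian spatial correlation."""
    z = rng.standard_normal(shape)
    if corr_len > 0:
        z = ndimage.gaussian_filter(z, sigma=corr_len, mode="reflect")
        sd = z.std()
        z = (z - z.mean()) / sd if sd > 0 else z * 0.0
    return z


def generate_basin_scheme(spec: SyntheticWorldSpec) -> BasinScheme:
    """Contiguous basin tessellation of the unmasked grid."""
    spec.validate()
    lat, lon = spec.grid()
    mask = spec.cell_mask()
    rng = np.random.default_rng([spec.seed, _STREAM_BASINS])
    raster = _region_grow(~mask, spec.n_basins, rng)
    areas = cell_area_grid(lat, lon, spec.resolution)
    return BasinScheme(
        basin_raster=raster,
        cell_areas=areas,
        earthquake_ids=frozenset(spec.earthquake_basins),
    )


def _draw_field(
    fs: FieldSpec, rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    z = _correlated_standard_field(rng, shape, fs.corr_len)
    if fs.dist == "lognormal":
        v = np.exp(np.log(fs.loc) + fs.scale * z)
    elif fs.dist == "gaussian":
        v = fs.loc + fs.scale * z
    else:  # beta: copula through the normal CDF keeps the correlation
        u = stats.norm.cdf(z)
        v = stats.beta.ppf(u, fs.loc, fs.scale)
    if fs.coverage < 1.0:
        gaps = rng.random(shape) > fs.coverage
        v = np.where(gaps, np.nan, v)
    return v


def generate_fields(
    spec: SyntheticWorldSpec, scheme: BasinScheme
) -> dict[str, GeoGrid]:
    """Draw all gridded inputs and apply planted-hotspot manipulations."""
    spec.validate()
    lat, lon = spec.grid()
    if scheme.cell_areas.shape != (lat.size, lon.size):
        raise InvalidSpecError("scheme grid does not match spec grid")
    mask = spec.cell_mask()
    shape = mask.shape
    fields: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for k, (name, fs) in enumerate(sorted(spec.field_params.items())):
        rng = np.random.default_rng([spec.seed, _STREAM_FIELDS + k])
        v = _draw_field(fs, rng, shape)
        v[mask] = np.nan
        fields[name] = v
        units[name] = fs.units

    if spec.planted_hotspots and "withdrawal" in fields and "streamflow" in fields:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = fields["withdrawal"] / fields["streamflow"]
        median_ratio = float(np.nanmedian(ratio))
    for hs in spec.planted_hotspots:
        cells = scheme.basin_raster == hs.basin_id
        if not cells.any():
            raise InvalidSpecError(f"planted basin {hs.basin_id} not in scheme")
        if "withdrawal" in fields and "streamflow" in fields:
            w, q = fields["withdrawal"], fields["streamflow"]
            w[cells] = (
                np.fmax(w[cells], median_ratio * q[cells]) * hs.stress_multiplier
            )
        if "tws_trend" in fields:
            fields["tws_trend"][cells] += hs.trend_offset
        if "adaptive_capacity" in fields:
            a = fields["adaptive_capacity"]
            a[cells] = np.minimum(a[cells], hs.adaptability_ceiling)
        for eco in ("eco_flow_sensitivity", "veg_water_sensitivity"):
            if eco in fields:
                v = fields[eco]
                floor = np.nanquantile(v, hs.sensitivity_floor)
                v[cells] = np.fmax(v[cells], floor)

    return {
        name: GeoGrid(values=v, lat=lat, lon=lon, units=units[name])
        for name, v in fields.items()
    }


def generate_nations(
    spec: SyntheticWorldSpec, scheme: BasinScheme
) -> tuple[np.ndarray, pd.DataFrame]:
    """Nation tessellation (every cell one nation) + national IWRM scores.

    Nations are grown independently of basins, so with n_nations >= 2 some
    basins straddle national borders (transboundary basins). IWRM scores
    are uniform on [0, 100].
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, _STREAM_NATIONS])
    all_valid = np.ones(scheme.basin_raster.shape, dtype=bool)
    nation_raster = _region_grow(all_valid, spec.n_nations, rng)
    score_rng = np.random.default_rng([spec.seed, _STREAM_SCORES])
    scores = pd.DataFrame(
        {
            "nation_id": np.arange(1, spec.n_nations + 1),
            "iwrm_score": score_rng.uniform(0.0, 100.0, spec.n_nations),
        }
    )
    return nation_raster, scores


def generate_wetlands(spec: SyntheticWorldSpec) -> np.ndarray:
    """Random (lon, lat) point layer standing in for significant wetlands."""
    rng = np.random.default_rng([spec.seed, _STREAM_WETLANDS])
    s, n = min(spec.lat_extent), max(spec.lat_extent)
    w, e = spec.lon_extent
    lons = rng.uniform(w, e, spec.n_wetlands)
    lats = rng.uniform(s, n, spec.n_wetlands)
    return np.column_stack([lons, lats])


@dataclass(frozen=True)
class SyntheticWorld:
    """A fully generated world: grids, basins, nations, and points."""

    spec: SyntheticWorldSpec
    scheme: BasinScheme
    fields: Mapping[str, GeoGrid]
    nation_raster: np.ndarray
    nation_scores: pd.DataFrame
    wetlands: np.ndarray

    def with_fields(self, fields: Mapping[str, GeoGrid]) -> "SyntheticWorld":
        merged = dict(self.fields)
        merged.update(fields)
        return replace(self, fields=merged)


def generate_world(spec: SyntheticWorldSpec) -> SyntheticWorld:
    """Generate basins, fields, nations, and wetlands from one seed."""
    spec.validate()
    scheme = generate_basin_scheme(spec)
    fields = generate_fields(spec, scheme)
    nation_raster, scores = generate_nations(spec, scheme)
    wetlands = generate_wetlands(spec)
    return SyntheticWorld(
        spec=spec,
        scheme=scheme,
        fields=fields,
        nation_raster=nation_raster,
        nation_scores=scores,
        wetlands=wetlands,
    )
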