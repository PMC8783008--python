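"""Regular lat-lon grids, cell areas, and basin-level aggregation.

All gridded inputs live on one regular lat-lon raster (rows = latitude,
descending; columns = longitude, ascending). Missing cells are NaN. Basins
are a whole-cell tessellation: every cell belongs to exactly one basin
(id >= 1) or is masked (id 0). Intensive properties are aggregated to the
basin scale by area-weighted means, extensive properties by within-basin
sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Authalic (equal-area) Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


class GridError(ValueError):
    """Raised for inconsistent grid geometry or grid/scheme mismatches."""


@dataclass(frozen=True)
class GeoGrid:
    """A 2-D field on a regular lat-lon grid.

    Parameters
    ----------
    values : ndarray, shape (nlat, nlon)
        Field values; NaN marks missing cells.
    lat : ndarray
        Cell-center latitudes in degrees, strictly descending, uniform step.
    lon : ndarray
        Cell-center longitudes in degrees, strictly ascending, uniform step.
    units : str
        Unit string carried as metadata (e.g. ``"mm yr-1"``).
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        if values.ndim != 2 or values.shape != (lat.size, lon.size):
            raise GridError(
                f"values shape {values.shape} does not match "
                f"(nlat={lat.size}, nlon={lon.size})"
            )
        if np.any(np.abs(lat) > 90.0):
            raise GridError("latitudes must lie in [-90, 90]")
        res = self._step(lat, descending=True)
        res_lon = self._step(lon, descending=False)
        if not np.isclose(res, res_lon, rtol=1e-9):
            raise GridError("lat and lon spacing differ")

    @staticmethod
    def _step(coords: np.ndarray, descending: bool) -> float:
        if coords.size < 2:
            raise GridError("grid needs at least 2 rows and 2 columns")
        d = np.diff(coords)
        if descending:
            d = -d
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-9):
            raise GridError("coordinates must be uniform and monotonic")
        return float(d[0])

    @property
    def resolution(self) -> float:
        """Grid spacing in degrees."""
        return self._step(self.lat, descending=True)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is missing."""
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray, units: str | None = None) -> "GeoGrid":
        """Return a new grid on the same geometry with different values."""
        return replace(
            self, values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
        )

    def same_geometry(self, other: "GeoGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )


def grid_coords(
    lat_extent: tuple[float, float],
    lon_extent: tuple[float, float],
    resolution: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinates for an extent; resolution must divide it."""
    if resolution <= 0:
        raise GridError("resolution must be positive")
    s, n = min(lat_extent), max(lat_extent)
    w, e = lon_extent
    nlat = (n - s) / resolution
    nlon = (e - w) / resolution
    if not (np.isclose(nlat, round(nlat)) and np.isclose(nlon, round(nlon))):
        raise GridError("resolution must divide both extents")
    nlat, nlon = int(round(nlat)), int(round(nlon))
    lat = n - resolution * (np.arange(nlat) + 0.5)
    lon = w + resolution * (np.arange(nlon) + 0.5)
    return lat, lon


def cell_area_grid(
    lat_centers: np.ndarray,
    lon_centers: np.ndarray,
    resolution: float | None = None,
) -> GeoGrid:
    """Cell areas (km^2) on an authalic sphere.

    area(lat) = R^2 * dlambda * (sin(top) - sin(bottom)); exact for a
    spherical Earth, within 0.3% of ellipsoidal areas at any latitude, and
    strictly decreasing with |lat|.
    """
    lat = np.asarray(lat_centers, dtype=float)
    lon = np.asarray(lon_centers, dtype=float)
    if resolution is None:
        resolution = GeoGrid._step(lat, descending=True)
    if resolution <= 0:
        raise GridError("resolution must be positive")
    if np.any(np.abs(lat) > 90.0):
        raise GridError("latitudes must lie in [-90, 90]")
    half = resolution / 2.0
    top = np.radians(np.clip(lat + half, -90.0, 90.0))
    bot = np.radians(np.clip(lat - half, -90.0, 90.0))
    dlam = np.radians(resolution)
    row_area = EARTH_RADIUS_KM**2 * dlam * (np.sin(top) - np.sin(bot))
    values = np.repeat(row_area[:, None], lon.size, axis=1)
    return GeoGrid(values=values, lat=lat, lon=lon, units="km2")


@dataclass(frozen=True)
class MaskReport:
    """Bookkeeping for basin masking: what survived the cut."""

    dropped_ids: tuple[int, ...]
    retained_count_fraction: float
    retained_area_fraction: float


@dataclass(frozen=True)
class BasinScheme:
    """Whole-cell assignment of grid cells to basins.

    ``basin_raster`` holds integer basin ids; 0 marks masked cells. Basin
    areas are the sums of member cell areas, so by construction basin areas
    partition the unmasked grid area exactly.
    """

    basin_raster: np.ndarray
    cell_areas: GeoGrid
    earthquake_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        raster = np.asarray(self.basin_raster)
        if not np.issubdtype(raster.dtype, np.integer):
            raster = raster.astype(np.int32)
        object.__setattr__(self, "basin_raster", raster)
        object.__setattr__(self, "earthquake_ids", frozenset(self.earthquake_ids))
        if raster.shape != self.cell_areas.shape:
            raise GridError("basin raster and cell-area grid shapes differ")
        if raster.min() < 0:
            raise GridError("basin ids must be >= 0 (0 = masked)")

    @property
    def basin_ids(self) -> np.ndarray:
        ids = np.unique(self.basin_raster)
        return ids[ids > 0]

    @property
    def n_basins(self) -> int:
        return int(self.basin_ids.size)

    @property
    def basin_areas(self) -> pd.Series:
        """Basin areas in km^2, indexed by basin id."""
        flat = self.basin_raster.ravel()
        sums = np.bincount(flat, weights=self.cell_areas.values.ravel())
        ids = self.basin_ids
        return pd.Series(sums[ids], index=pd.Index(ids, name="basin_id"),
                         name="area_km2")

    def check_grid(self, grid: GeoGrid) -> None:
        if not grid.same_geometry(self.cell_areas):
            raise GridError("field grid does not match basin scheme grid")


def basin_mean_intensive(field: GeoGrid, scheme: BasinScheme) -> pd.Series:
    """Area-weighted basin means of an intensive field.

    Missing cells are excluded from numerator and denominator; a basin with
    no valid cell is NaN.
    """
    scheme.check_grid(field)
    ids = scheme.basin_raster.ravel()
    v = field.values.ravel()
    a = scheme.cell_areas.values.ravel()
    ok = (ids > 0) & np.isfinite(v)
    n = int(scheme.basin_raster.max()) + 1
    wsum = np.bincount(ids[ok], weights=(v * a)[ok], minlength=n)
    asum = np.bincount(ids[ok], weights=a[ok], minlength=n)
    out_ids = scheme.basin_ids
    with np.errstate(invalid="ignore", divide="ignore"):
        means = wsum[out_ids] / asum[out_ids]
    means[asum[out_ids] == 0] = np.nan
    return pd.Series(means, index=pd.Index(out_ids, name="basin_id"))


def basin_sum_extensive(field: GeoGrid, scheme: BasinScheme) -> pd.Series:
    """Within-basin sums of an extensive (per-cell absolute) field."""
    scheme.check_grid(field)
    ids = scheme.basin_raster.ravel()
    v = field.values.ravel()
    ok = (ids > 0) & np.isfinite(v)
    n = int(scheme.basin_raster.max()) + 1
    sums = np.bincount(ids[ok], weights=v[ok], minlength=n)
    out_ids = scheme.basin_ids
    return pd.Series(sums[out_ids], index=pd.Index(out_ids, name="basin_id"))


def mask_basins(
    scheme: BasinScheme, drop_ids: Iterable[int]
) -> tuple[BasinScheme, MaskReport]:
    """Remove basins from the scheme; dropped cells become masked (id 0)."""
    drop = sorted(set(int(i) for i in drop_ids))
    known = set(scheme.basin_ids.tolist())
    unknown = [i for i in drop if i not in known]
    if unknown:
        raise KeyError(f"unknown basin ids: {unknown}")
    areas = scheme.basin_areas
    raster = scheme.basin_raster.copy()
    if drop:
        raster[np.isin(raster, drop)] = 0
    kept = len(known) - len(drop)
    retained_area = float(areas.drop(drop).sum() / areas.sum()) if len(known) else 1.0
    report = MaskReport(
        dropped_ids=tuple(drop),
        retained_count_fraction=kept / len(known) if known else 1.0,
        retained_area_fraction=retained_area,
    )
    new = BasinScheme(
        basin_raster=raster,
        cell_areas=scheme.cell_areas,
        earthquake_ids=scheme.earthquake_ids - set(drop),
    )
    return new, report


@dataclass(frozen=True)
class PointOverlay:
    """Per-basin point counts plus points that fell outside the grid."""

    counts: pd.Series
    n_out_of_extent: int


def points_in_basins(
    points: Sequence[tuple[float, float]] | np.ndarray, scheme: BasinScheme
) -> PointOverlay:
    """Assign (lon, lat) points to basins via their containing cell.

    Cell ownership is half-open: west and south edges inclusive, east and
    north exclusive. Out-of-extent points are counted, never dropped
    silently. Points over masked cells land in the id-0 bucket and are
    excluded from per-basin counts.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return PointOverlay(
            counts=pd.Series(0, index=pd.Index(scheme.basin_ids, name="basin_id")),
            n_out_of_extent=0,
        )
    lon_pts, lat_pts = pts[:, 0], pts[:, 1]
    areas = scheme.cell_areas
    res = areas.resolution
    west = areas.lon[0] - res / 2
    south = areas.lat[-1] - res / 2
    nlat, nlon = areas.shape
    # indexing from the south/west edges makes those edges inclusive
    j = np.floor((lon_pts - west) / res).astype(int)
    i_s = np.floor((lat_pts - south) / res).astype(int)
    i = nlat - 1 - i_s
    inside = (j >= 0) & (j < nlon) & (i >= 0) & (i < nlat)
    ids = scheme.basin_raster[i[inside], j[inside]]
    n = int(scheme.basin_raster.max()) + 1
    counts = np.bincount(ids, minlength=n)
    out_ids = scheme.basin_ids
    return PointOverlay(
        counts=pd.Series(counts[out_ids],
                         index=pd.Index(out_ids, name="basin_id")),
        n_out_of_extent=int((~inside).sum()),
    )


def nation_overlap_fractions(
    scheme: BasinScheme, nation_raster: np.ndarray
) -> pd.DataFrame:
    """Area fraction of each basin lying in each nation.

    Returns a long-format frame (basin_id, nation_id, fraction); fractions
    per basin sum to 1 over the basin's unmasked cells.
    """
    raster = np.asarray(nation_raster)
    if raster.shape != scheme.basin_raster.shape:
        raise GridError("nation raster shape does not match scheme")
    b = scheme.basin_raster.ravel()
    nmap = raster.ravel()
    a = scheme.cell_areas.values.ravel()
    ok = b > 0
    df = pd.DataFrame({"basin_id": b[ok], "nation_id": nmap[ok], "area": a[ok]})
    g = df.groupby(["basin_id", "nation_id"], sort=True)["area"].sum().reset_index()
    totals = g.groupby("basin_id")["area"].transform("sum")
    g["fraction"] = g["area"] / totals
    return g[["basin_id", "nation_id", "fraction"]]
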