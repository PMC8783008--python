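"""Fixture-bundle I/O: write a synthetic world to disk and read it back.

Layout of a bundle directory:

* ``fields.nc`` — all gridded inputs plus the basin and nation integer
  rasters, CF-style lat/lon coordinates, units attributes (NetCDF, written
  through xarray's scipy backend).
* ``basins.geojson`` / ``nations.geojson`` — dissolved cell polygons per
  basin/nation (WGS84, lon/lat order) with id and area attributes.
* ``nation_scores.csv``, ``wetlands.csv`` — tables.
* ``spec.json`` — the generating specification, including the seed.
* ``manifest.json`` — file list with SHA-256 checksums.

Round-tripping a bundle reproduces raster values exactly (float64 is stored
losslessly) and tables byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grid import BasinScheme, GeoGrid, cell_area_grid
from .synthetic import FieldSpec, PlantedHotspot, SyntheticWorld, SyntheticWorldSpec


class BundleError(RuntimeError):
    """Raised for unreadable or tampered fixture bundles."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _dissolve_regions(
    raster: np.ndarray, lat: np.ndarray, lon: np.ndarray, resolution: float
) -> dict[int, object]:
    """Union of cell boxes per region id (id 0 skipped)."""
    half = resolution / 2.0
    out = {}
    for rid in np.unique(raster):
        if rid == 0:
            continue
        ii, jj = np.nonzero(raster == rid)
        cells = [
            box(lon[j] - half, lat[i] - half, lon[j] + half, lat[i] + half)
            for i, j in zip(ii, jj)
        ]
        out[int(rid)] = unary_union(cells)
    return out


def _write_geojson(path: Path, geoms: dict[int, object], properties: dict[int, dict]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"id": rid, **properties.get(rid, {})},
        }
        for rid, geom in sorted(geoms.items())
    ]
    payload = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")


def write_fixture_bundle(world: SyntheticWorld, directory: str | Path) -> dict:
    """Write the world to ``directory``; returns (and writes) the manifest."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise BundleError(f"cannot create bundle directory {directory}: {exc}") from exc

    some = next(iter(world.fields.values()))
    lat, lon = some.lat, some.lon
    data_vars = {
        name: xr.DataArray(
            g.values, dims=("lat", "lon"), attrs={"units": g.units}
        )
        for name, g in sorted(world.fields.items())
    }
    data_vars["basin_id"] = xr.DataArray(
        world.scheme.basin_raster.astype(np.int32), dims=("lat", "lon"),
        attrs={"long_name": "basin id (0 = masked)"},
    )
    data_vars["nation_id"] = xr.DataArray(
        world.nation_raster.astype(np.int32), dims=("lat", "lon"),
        attrs={"long_name": "nation id"},
    )
    ds = xr.Dataset(
        data_vars,
        coords={
            "lat": ("lat", lat, {"units": "degrees_north"}),
            "lon": ("lon", lon, {"units": "degrees_east"}),
        },
        attrs={"seed": int(world.spec.seed)},
    )
    files = {}
    nc_path = directory / "fields.nc"
    ds.to_netcdf(nc_path, engine="scipy")
    files["fields.nc"] = nc_path

    res = world.spec.resolution
    basin_geoms = _dissolve_regions(world.scheme.basin_raster, lat, lon, res)
    areas = world.scheme.basin_areas
    eq = world.scheme.earthquake_ids
    basin_props = {
        rid: {"area_km2": float(areas[rid]), "earthquake": rid in eq}
        for rid in basin_geoms
    }
    basins_path = directory / "basins.geojson"
    _write_geojson(basins_path, basin_geoms, basin_props)
    files["basins.geojson"] = basins_path

    nation_geoms = _dissolve_regions(world.nation_raster, lat, lon, res)
    score_map = world.nation_scores.set_index("nation_id")["iwrm_score"]
    nation_props = {rid: {"iwrm_score": float(score_map[rid])} for rid in nation_geoms}
    nations_path = directory / "nations.geojson"
    _write_geojson(nations_path, nation_geoms, nation_props)
    files["nations.geojson"] = nations_path

    scores_path = directory / "nation_scores.csv"
    world.nation_scores.to_csv(scores_path, index=False, float_format="%.17g")
    files["nation_scores.csv"] = scores_path

    wetlands_path = directory / "wetlands.csv"
    pd.DataFrame(world.wetlands, columns=["lon", "lat"]).to_csv(
        wetlands_path, index=False, float_format="%.17g"
    )
    files["wetlands.csv"] = wetlands_path

    spec_path = directory / "spec.json"
    spec_path.write_text(spec_to_json(world.spec), encoding="utf-8")
    files["spec.json"] = spec_path

    manifest = {
        "seed": int(world.spec.seed),
        "files": {name: _sha256(path) for name, path in files.items()},
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest


def verify_bundle(directory: str | Path) -> dict:
    """Check every file against the manifest; raise BundleError on mismatch."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise BundleError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    for name, checksum in manifest["files"].items():
        path = directory / name
        if not path.exists():
            raise BundleError(f"missing bundle file: {path}")
        actual = _sha256(path)
        if actual != checksum:
            raise BundleError(f"checksum mismatch for {path}")
    return manifest


def read_fixture_bundle(directory: str | Path, verify: bool = True) -> SyntheticWorld:
    """Read a bundle back into a SyntheticWorld (checksums verified)."""
    directory = Path(directory)
    if verify:
        verify_bundle(directory)
    spec = spec_from_json((directory / "spec.json").read_text(encoding="utf-8"))
    with xr.open_dataset(directory / "fields.nc", engine="scipy") as ds:
        ds = ds.load()
    lat = ds["lat"].values
    lon = ds["lon"].values
    fields = {}
    for name, da in ds.data_vars.items():
        if name in ("basin_id", "nation_id"):
            continue
        fields[name] = GeoGrid(
            values=da.values, lat=lat, lon=lon, units=da.attrs.get("units", "")
        )
    areas = cell_area_grid(lat, lon)
    scheme = BasinScheme(
        basin_raster=ds["basin_id"].values.astype(np.int32),
        cell_areas=areas,
        earthquake_ids=frozenset(spec.earthquake_basins),
    )
    scores = pd.read_csv(directory / "nation_scores.csv",
                         float_precision="round_trip")
    wetlands = pd.read_csv(directory / "wetlands.csv",
                           float_precision="round_trip")[["lon", "lat"]].to_numpy()
    return SyntheticWorld(
        spec=spec,
        scheme=scheme,
        fields=fields,
        nation_raster=ds["nation_id"].values.astype(np.int32),
        nation_scores=scores,
        wetlands=wetlands,
    )


def spec_to_json(spec: SyntheticWorldSpec) -> str:
    d = dataclasses.asdict(spec)
    d["field_params"] = {k: dataclasses.asdict(v) for k, v in spec.field_params.items()}
    d["planted_hotspots"] = [dataclasses.asdict(h) for h in spec.planted_hotspots]
    return json.dumps(d, indent=2, sort_keys=True)


def spec_from_json(text: str) -> SyntheticWorldSpec:
    d = json.loads(text)
    d["field_params"] = {k: FieldSpec(**v) for k, v in d["field_params"].items()}
    d["planted_hotspots"] = tuple(
        PlantedHotspot(**h) for h in d["planted_hotspots"]
    )
    d["lat_extent"] = tuple(d["lat_extent"])
    d["lon_extent"] = tuple(d["lon_extent"])
    d["earthquake_basins"] = tuple(d["earthquake_basins"])
    return SyntheticWorldSpec(**d)
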