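import numpy as np
import pandas as pd
import pytest

import basinvuln as bv
from basinvuln.grid import GridError, MaskReport

from conftest import loop_basin_mean, loop_basin_sum


def global_half_degree():
    return bv.grid_coords((-90.0, 90.0), (-180.0, 180.0), 0.5)


class TestCellArea:
    def test_global_sum_matches_sphere_surface(self):
        lat, lon = global_half_degree()
        areas = bv.cell_area_grid(lat, lon, 0.5)
        sphere = 4.0 * np.pi * bv.EARTH_RADIUS_KM**2
        assert abs(areas.values.sum() - sphere) / sphere < 1e-3

    def test_registration_of_global_grid(self):
        lat, lon = global_half_degree()
        assert lat[0] == 89.75 and lat[-1] == -89.75
        assert lon[0] == -179.75 and lon[-1] == 179.75

    def test_equator_to_60deg_ratio_near_two(self):
        lat, lon = global_half_degree()
        areas = bv.cell_area_grid(lat, lon, 0.5)
        eq = areas.values[np.argmin(np.abs(lat - 0.25)), 0]
        mid = areas.values[np.argmin(np.abs(lat - 60.25)), 0]
        # cos(60deg) scaling for small cells: ratio approx 2
        assert eq / mid == pytest.approx(1.0 / np.cos(np.radians(60.25)), rel=1e-2)

    def test_mirrored_latitudes_equal_and_monotone(self):
        lat, lon = global_half_degree()
        areas = bv.cell_area_grid(lat, lon, 0.5)
        col = areas.values[:, 0]
        assert np.allclose(col, col[::-1], rtol=0, atol=1e-9)
        north = col[: len(col) // 2]  # descending |lat| -> increasing area
        assert np.all(np.diff(north) > 0)

    def test_bad_resolution_rejected(self):
        with pytest.raises(GridError):
            bv.cell_area_grid(np.array([10.0, 9.5]), np.array([0.0, 0.5]), -0.5)


def _toy_scheme():
    """2x4 grid at the equator (equal cell areas), two basins."""
    lat, lon = bv.grid_coords((-0.5, 0.5), (0.0, 2.0), 0.5)
    areas = bv.cell_area_grid(lat, lon, 0.5)
    raster = np.array([[1, 1, 2, 2], [1, 1, 2, 2]])
    return bv.BasinScheme(basin_raster=raster, cell_areas=areas), lat, lon


class TestBasinAggregation:
    def test_constant_field_mean_is_constant(self):
        scheme, lat, lon = _toy_scheme()
        f = bv.GeoGrid(np.full((2, 4), 7.5), lat, lon)
        means = bv.basin_mean_intensive(f, scheme)
        assert np.allclose(means.to_numpy(), 7.5)

    def test_two_equal_area_cells_average(self):
        scheme, lat, lon = _toy_scheme()
        v = np.full((2, 4), np.nan)
        v[0, 0], v[1, 0] = 1.0, 3.0
        means = bv.basin_mean_intensive(bv.GeoGrid(v, lat, lon), scheme)
        assert means[1] == pytest.approx(2.0, abs=1e-12)
        assert np.isnan(means[2])  # no valid cells -> missing

    def test_extensive_all_ones_counts_cells(self):
        scheme, lat, lon = _toy_scheme()
        sums = bv.basin_sum_extensive(bv.GeoGrid(np.ones((2, 4)), lat, lon), scheme)
        assert sums[1] == 4 and sums[2] == 4

    def test_partition_conservation(self, small_world):
        f = small_world.fields["population"]
        sums = bv.basin_sum_extensive(f, small_world.scheme)
        unmasked = small_world.scheme.basin_raster > 0
        total = np.nansum(f.values[unmasked])
        assert sums.sum() == pytest.approx(total, rel=1e-12)

    def test_mean_matches_loop_oracle(self, small_world):
        f = small_world.fields["streamflow"]
        fast = bv.basin_mean_intensive(f, small_world.scheme)
        slow = loop_basin_mean(f, small_world.scheme)
        for bid, v in slow.items():
            assert fast[bid] == pytest.approx(v, rel=1e-12)

    def test_sum_matches_loop_oracle(self, small_world):
        f = small_world.fields["gdp"]
        fast = bv.basin_sum_extensive(f, small_world.scheme)
        slow = loop_basin_sum(f, small_world.scheme)
        for bid, v in slow.items():
            assert fast[bid] == pytest.approx(v, rel=1e-12)

    def test_mean_linearity(self, small_world):
        f = small_world.fields["tws_trend"]
        scheme = small_world.scheme
        base = bv.basin_mean_intensive(f, scheme)
        scaled = bv.basin_mean_intensive(f.with_values(2.5 * f.values - 3.0), scheme)
        assert np.allclose(scaled.to_numpy(), 2.5 * base.to_numpy() - 3.0,
                           rtol=1e-12, atol=1e-12, equal_nan=True)

    def test_grid_mismatch_rejected(self, small_world):
        lat, lon = bv.grid_coords((-0.5, 0.5), (0.0, 2.0), 0.5)
        alien = bv.GeoGrid(np.ones((2, 4)), lat, lon)
        with pytest.raises(GridError):
            bv.basin_mean_intensive(alien, small_world.scheme)

    def test_basin_areas_partition_grid(self, small_world):
        scheme = small_world.scheme
        unmasked_area = scheme.cell_areas.values[scheme.basin_raster > 0].sum()
        assert scheme.basin_areas.sum() == pytest.approx(unmasked_area, rel=1e-9)


class TestMaskBasins:
    def test_drop_none_is_identity(self, small_world):
        new, report = bv.mask_basins(small_world.scheme, [])
        assert np.array_equal(new.basin_raster, small_world.scheme.basin_raster)
        assert report == MaskReport((), 1.0, 1.0)

    def test_drop_one_of_four_equal_area(self):
        scheme, _, _ = _toy_scheme()
        # split into 4 single-column basins of equal area
        raster = np.tile(np.array([1, 2, 3, 4]), (2, 1))
        scheme = bv.BasinScheme(basin_raster=raster, cell_areas=scheme.cell_areas)
        new, report = bv.mask_basins(scheme, [2])
        assert report.retained_count_fraction == pytest.approx(0.75)
        assert report.retained_area_fraction == pytest.approx(0.75, rel=1e-9)
        assert 2 not in new.basin_ids

    def test_idempotent(self, small_world):
        drop = [int(small_world.scheme.basin_ids[0])]
        once, _ = bv.mask_basins(small_world.scheme, drop)
        # dropping an already-removed id is an error; re-masking nothing is a no-op
        twice, rep = bv.mask_basins(once, [])
        assert np.array_equal(once.basin_raster, twice.basin_raster)
        assert rep.retained_count_fraction == 1.0

    def test_unknown_id_lists_offenders(self, small_world):
        with pytest.raises(KeyError, match="9999"):
            bv.mask_basins(small_world.scheme, [9999])


class TestPointsInBasins:
    def test_cell_center_point(self):
        scheme, lat, lon = _toy_scheme()
        res = bv.points_in_basins([(lon[2], lat[0])], scheme)
        assert res.counts[2] == 1 and res.counts[1] == 0
        assert res.n_out_of_extent == 0

    def test_counts_plus_out_of_extent_conserved(self, small_world):
        rng = np.random.default_rng(11)
        pts = np.column_stack([rng.uniform(-2, 12, 100), rng.uniform(-7, 7, 100)])
        res = bv.points_in_basins(pts, small_world.scheme)
        masked = 100 - res.n_out_of_extent - int(res.counts.sum())
        assert masked >= 0  # masked-cell hits are excluded from basin counts
        # every in-extent point lands in exactly one cell
        in_extent = (
            (pts[:, 0] >= 0) & (pts[:, 0] < 10) & (pts[:, 1] >= -5) & (pts[:, 1] < 5)
        )
        assert res.n_out_of_extent == int((~in_extent).sum())

    def test_boundary_point_west_south_inclusive(self):
        scheme, lat, lon = _toy_scheme()
        # lon=1.0 is the west edge of column 2 (basin 2); lat=0.0 is the
        # south edge of row 0
        res = bv.points_in_basins([(1.0, 0.0)], scheme)
        assert res.counts[2] == 1

    def test_empty_points(self, small_world):
        res = bv.points_in_basins(np.empty((0, 2)), small_world.scheme)
        assert res.counts.sum() == 0 and res.n_out_of_extent == 0


class TestNationOverlaps:
    def test_fractions_sum_to_one(self, small_world):
        ov = bv.nation_overlap_fractions(small_world.scheme, small_world.nation_raster)
        sums = ov.groupby("basin_id")["fraction"].sum()
        assert np.allclose(sums.to_numpy(), 1.0, atol=1e-9)

    def test_single_nation_world(self, small_world):
        one = np.ones_like(small_world.nation_raster)
        ov = bv.nation_overlap_fractions(small_world.scheme, one)
        assert (ov.groupby("basin_id").size() == 1).all()
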