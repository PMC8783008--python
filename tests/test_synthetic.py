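import numpy as np
import pytest
from scipy import ndimage

import basinvuln as bv
from basinvuln.synthetic import InvalidSpecError

from conftest import small_spec


class TestSpecValidation:
    def test_too_many_basins_rejected(self):
        spec = small_spec().replace(n_basins=10_000)
        with pytest.raises(InvalidSpecError, match="n_basins"):
            spec.validate()

    def test_nonpositive_streamflow_scale_rejected(self):
        params = bv.default_field_params()
        params["streamflow"] = bv.FieldSpec("lognormal", -5.0, 1.0)
        with pytest.raises(InvalidSpecError, match="streamflow"):
            small_spec().replace(field_params=params).validate()

    def test_resolution_must_divide_extent(self):
        with pytest.raises(Exception):
            small_spec().replace(lat_extent=(-5.0, 5.3)).validate()


class TestBasinScheme:
    def test_partition_and_area_conservation(self):
        spec = small_spec().replace(mask_rows_fraction=0.0, n_basins=4,
                                    lat_extent=(-2.5, 2.5), lon_extent=(0.0, 5.0))
        scheme = bv.generate_basin_scheme(spec)
        assert scheme.n_basins == 4
        assert (scheme.basin_raster > 0).all()
        total = scheme.cell_areas.values.sum()
        assert scheme.basin_areas.sum() == pytest.approx(total, rel=1e-9)

    def test_single_basin_world(self):
        spec = small_spec().replace(n_basins=1, mask_rows_fraction=0.0)
        scheme = bv.generate_basin_scheme(spec)
        assert np.all(scheme.basin_raster == 1)

    def test_determinism(self):
        a = bv.generate_basin_scheme(small_spec())
        b = bv.generate_basin_scheme(small_spec())
        assert np.array_equal(a.basin_raster, b.basin_raster)

    def test_basins_contiguous(self, small_world):
        raster = small_world.scheme.basin_raster
        for bid in small_world.scheme.basin_ids:
            _, n = ndimage.label(raster == bid)
            assert n == 1, f"basin {bid} is fragmented"

    def test_masked_rows_have_no_basin(self, small_world):
        mask = small_world.spec.cell_mask()
        assert (small_world.scheme.basin_raster[mask] == 0).all()


class TestFields:
    def test_support_constraints(self, small_world):
        f = small_world.fields
        assert np.nanmin(f["streamflow"].values) > 0
        a = f["adaptive_capacity"].values
        assert np.nanmin(a) >= 0 and np.nanmax(a) <= 1
        for eco in ("eco_flow_sensitivity", "veg_water_sensitivity"):
            assert np.nanmin(f[eco].values) >= 0

    def test_units_carried(self, small_world):
        assert small_world.fields["withdrawal"].units == "mm yr-1"
        assert small_world.fields["tws_trend"].units == "mm yr-1"

    def test_stress_ratio_spans_unit_interval_and_beyond(self, default_world):
        w = default_world.fields["withdrawal"].values
        q = default_world.fields["streamflow"].values
        r = w / q
        assert np.nanmin(r) < 0.01 and np.nanmax(r) > 1.0

    def test_partial_coverage_of_head_decline_proxy(self, default_world):
        v = default_world.fields["eco_flow_sensitivity"].values
        unmasked = ~default_world.spec.cell_mask()
        frac_valid = np.isfinite(v[unmasked]).mean()
        assert 0.4 < frac_valid < 0.8  # coverage parameter 0.6

    def test_zero_correlation_length_gives_independent_cells(self):
        params = bv.default_field_params()
        params["tws_trend"] = bv.FieldSpec("gaussian", 0.0, 8.0, corr_len=0.0,
                                           units="mm yr-1")
        spec = bv.SyntheticWorldSpec(
            seed=5, n_basins=10, lat_extent=(-25.0, 25.0),
            lon_extent=(0.0, 50.0), mask_rows_fraction=0.0,
            field_params=params,
        )  # 100 x 100 = 1e4 cells
        world = bv.generate_world(spec)
        v = world.fields["tws_trend"].values
        r = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.05

    def test_positive_correlation_length_smooths(self, default_world):
        v = default_world.fields["tws_trend"].values
        ok = np.isfinite(v[:, :-1]) & np.isfinite(v[:, 1:])
        r = np.corrcoef(v[:, :-1][ok], v[:, 1:][ok])[0, 1]
        assert r > 0.5

    def test_determinism_bitwise(self):
        a = bv.generate_world(small_spec())
        b = bv.generate_world(small_spec())
        for name in a.fields:
            assert np.array_equal(
                a.fields[name].values, b.fields[name].values, equal_nan=True
            )
        assert np.array_equal(a.nation_raster, b.nation_raster)
        assert a.nation_scores.equals(b.nation_scores)
        assert np.array_equal(a.wetlands, b.wetlands)


class TestPlantedHotspots:
    def test_planted_basin_exceeds_nonplanted_medians(self):
        planted = (bv.PlantedHotspot(basin_id=7, stress_multiplier=10.0,
                                     trend_offset=-50.0),)
        spec = small_spec().replace(planted_hotspots=planted)
        world = bv.generate_world(spec)
        table = bv.basin_forcings(world, bv.PipelineConfig())
        ratio = table["W"] / table["Q"]
        others = table.drop(7)
        assert ratio[7] > (others["W"] / others["Q"]).median()
        assert table.loc[7, "dTWS_dt"] < others["dTWS_dt"].median()

    def test_adaptability_ceiling_and_sensitivity_floor(self):
        planted = (bv.PlantedHotspot(basin_id=3, adaptability_ceiling=0.15,
                                     sensitivity_floor=0.9),)
        world = bv.generate_world(small_spec().replace(planted_hotspots=planted))
        unplanted = bv.generate_world(small_spec())
        cells = world.scheme.basin_raster == 3
        assert np.nanmax(world.fields["adaptive_capacity"].values[cells]) <= 0.15
        veg = world.fields["veg_water_sensitivity"].values
        # the floor is the 0.9 quantile of the pristine (unplanted) field
        floor = np.nanquantile(unplanted.fields["veg_water_sensitivity"].values, 0.9)
        assert np.nanmin(veg[cells]) >= floor

    def test_unknown_planted_basin_rejected(self):
        spec = small_spec().replace(
            planted_hotspots=(bv.PlantedHotspot(basin_id=999),)
        )
        scheme = bv.generate_basin_scheme(spec)
        with pytest.raises(InvalidSpecError, match="999"):
            bv.generate_fields(spec, scheme)


class TestNations:
    def test_single_nation_means_no_transboundary(self, small_world):
        spec = small_spec().replace(n_nations=1)
        world = bv.generate_world(spec)
        ov = bv.nation_overlap_fractions(world.scheme, world.nation_raster)
        n_nations = ov.groupby("basin_id")["nation_id"].nunique()
        assert (n_nations == 1).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_many_nations_yield_transboundary_basins(self, seed):
        spec = small_spec(seed=seed).replace(n_nations=60)
        world = bv.generate_world(spec)
        ov = bv.nation_overlap_fractions(world.scheme, world.nation_raster)
        n_nations = ov.groupby("basin_id")["nation_id"].nunique()
        assert (n_nations >= 2).any()

    def test_scores_in_range(self, small_world):
        s = small_world.nation_scores["iwrm_score"]
        assert s.min() >= 0 and s.max() <= 100

    def test_every_cell_has_a_nation(self, small_world):
        assert (small_world.nation_raster > 0).all()
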