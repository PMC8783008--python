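"""End-to-end pipeline: gridded inputs -> per-basin vulnerability table.

Order of operations: (1) basin-aggregate withdrawal, streamflow, storage
trend, adaptive capacity (area-weighted means of intensive fields);
(2) percentile-transform the two ecological fields at the grid scale, basin
average, combine, max-normalize into E; (3) compute F, T, B (with the
earthquake fallback B = F); (4) S by fuzzy sum, V = S*B; (5) Head/Tail
Breaks classification into low / transitional / high / very high; plus the
categorical stress x trend co-occurrence label and extensive sums for
exposure accounting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .grid import basin_mean_intensive, basin_sum_extensive, points_in_basins
from .indicators import (
    basin_status,
    cooccurrence_class,
    stress_indicator,
    stress_ratio,
    trend_indicator,
)
from .sensitivity import (
    area_weighted_percentile_transform,
    ecological_sensitivity,
    rescale_unit,
)
from .synthetic import EXTENSIVE_FIELDS, SyntheticWorld
from .vulnerability import classify_vulnerability


def basin_forcings(world: SyntheticWorld, config: PipelineConfig) -> pd.DataFrame:
    """Aggregate gridded inputs to the basin scale (indicator inputs only)."""
    scheme = world.scheme
    f = world.fields
    table = pd.DataFrame(
        {
            "W": basin_mean_intensive(f["withdrawal"], scheme),
            "Q": basin_mean_intensive(f["streamflow"], scheme),
            "dTWS_dt": basin_mean_intensive(f["tws_trend"], scheme),
            "A": basin_mean_intensive(f["adaptive_capacity"], scheme),
        }
    )
    if config.adaptive_rescale:
        table["A"] = rescale_unit(table["A"])
    areas = scheme.cell_areas
    p1 = area_weighted_percentile_transform(
        f["eco_flow_sensitivity"], areas, config.percentile_bins, config.tie_rule
    )
    p2 = area_weighted_percentile_transform(
        f["veg_water_sensitivity"], areas, config.percentile_bins, config.tie_rule
    )
    table["E"] = ecological_sensitivity(p1, p2, scheme, combine=config.eco_combine)
    table["earthquake"] = np.isin(table.index, sorted(scheme.earthquake_ids))
    table["area_km2"] = scheme.basin_areas
    return table


def run_pipeline(world: SyntheticWorld, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Full analysis on one world; returns the per-basin table.

    Columns: forcings (W, Q, dTWS_dt, A, E, area_km2, earthquake), derived
    indicators (stress_ratio, F, T, B, S, V), classification (vclass,
    class_label, hotspot, cooccurrence), and extensive sums plus wetland
    counts where the world carries them. Basins with Q <= 0 are unscorable:
    indicator columns are NaN and vclass is 0.
    """
    config = config or PipelineConfig()
    table = basin_forcings(world, config)
    W = table["W"].to_numpy()
    Q = table["Q"].to_numpy()
    trend = table["dTWS_dt"].to_numpy()
    eq = table["earthquake"].to_numpy()

    table["stress_ratio"] = stress_ratio(W, Q)
    table["F"] = stress_indicator(W, Q, config.norm_factor)
    table["T"] = trend_indicator(trend, Q, config.norm_factor)
    table["B"] = basin_status(table["F"].to_numpy(), table["T"].to_numpy(), eq)
    table["cooccurrence"] = cooccurrence_class(
        table["stress_ratio"].to_numpy(),
        trend,
        thresholds=config.stress_thresholds,
        trend_threshold=config.trend_threshold,
        strict=config.stress_strict,
    )

    classified = classify_vulnerability(table, variant=config.variant, config=config)
    table = table.join(classified.drop(columns=["variant"]))
    table = table.rename(columns={"S_variant": "S"})
    table["variant"] = config.variant

    for name in EXTENSIVE_FIELDS:
        if name in world.fields:
            table[name] = basin_sum_extensive(world.fields[name], world.scheme)
    if "species_richness" in world.fields:
        table["species_richness"] = basin_mean_intensive(
            world.fields["species_richness"], world.scheme
        )
    if world.wetlands is not None and len(world.wetlands):
        table["wetlands"] = points_in_basins(world.wetlands, world.scheme).counts
    return table


def write_basin_table(table: pd.DataFrame, path) -> None:
    """Write the per-basin table as CSV with a stable column order."""
    table.to_csv(path, index=True, float_format="%.12g")
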