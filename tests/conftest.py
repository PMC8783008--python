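import numpy as np
import pytest

import basinvuln as bv


def small_spec(seed: int = 3) -> bv.SyntheticWorldSpec:
    """A 400-cell, 50-basin world: cheap enough for brute-force oracles."""
    return bv.SyntheticWorldSpec(
        seed=seed,
        n_basins=50,
        lat_extent=(-5.0, 5.0),
        lon_extent=(0.0, 10.0),
        n_nations=4,
        n_wetlands=50,
    )


@pytest.fixture(scope="session")
def small_world():
    return bv.generate_world(small_spec())


@pytest.fixture(scope="session")
def default_world():
    """The default 200-basin, 8000-cell world (seed 1)."""
    return bv.generate_world(bv.SyntheticWorldSpec(seed=1))


@pytest.fixture(scope="session")
def basin_table(default_world):
    return bv.run_pipeline(default_world)


# ---------------------------------------------------------------- oracles


def loop_basin_mean(field, scheme):
    """Cell-by-cell area-weighted mean, independent of the bincount path."""
    out = {}
    nlat, nlon = field.shape
    for bid in scheme.basin_ids:
        num = den = 0.0
        for i in range(nlat):
            for j in range(nlon):
                if scheme.basin_raster[i, j] == bid and np.isfinite(
                    field.values[i, j]
                ):
                    a = scheme.cell_areas.values[i, j]
                    num += field.values[i, j] * a
                    den += a
        out[int(bid)] = num / den if den > 0 else np.nan
    return out


def loop_basin_sum(field, scheme):
    out = {}
    nlat, nlon = field.shape
    for bid in scheme.basin_ids:
        s = 0.0
        for i in range(nlat):
            for j in range(nlon):
                if scheme.basin_raster[i, j] == bid and np.isfinite(
                    field.values[i, j]
                ):
                    s += field.values[i, j]
        out[int(bid)] = s
    return out


def loop_percentile(values, areas, bins=100):
    """O(n^2) per-cell percentile: for each cell, sum areas below/at it."""
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    total = areas.sum()
    out = np.empty_like(values)
    for k, v in enumerate(values):
        lo = areas[values < v].sum()
        hi = lo + areas[values == v].sum()
        mid = (lo + hi) / 2.0
        out[k] = min(max(np.ceil(mid / total * bins) / bins, 1.0 / bins), 1.0)
    return out


def naive_head_tail(values, iterations=3):
    """Plain-Python recursive mean partition."""
    vals = [float(v) for v in np.asarray(values).ravel()]
    breaks = []
    current = vals
    for _ in range(iterations):
        m = sum(current) / len(current)
        head = [v for v in current if v > m]
        if not head or len(head) == len(current):
            break
        breaks.append(m)
        if len(head) < 2 or len(set(head)) == 1:
            break
        current = head
    labels = [1 + sum(v > b for b in breaks) for v in vals]
    return breaks, labels
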