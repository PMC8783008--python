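"""Ecological and social-ecological sensitivity indicators.

Two gridded ecological datasets of incommensurable units (an
environmental-flow head-decline proxy and a vegetation water-sensitivity
proxy) are made comparable by an area-weighted percentile transform, basin
averaged, combined, and max-normalized so the most sensitive basin scores
exactly 1. Social adaptive capacity A (ability to respond to disturbances,
[0,1]) is inverted to 1-A and merged with ecological sensitivity through
the fuzzy sum, which never falls below its largest input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import BasinScheme, GeoGrid, basin_mean_intensive


def area_weighted_percentile_transform(
    field: GeoGrid,
    areas: GeoGrid,
    bins: int = 100,
    tie_rule: str = "midpoint",
) -> GeoGrid:
    """Map each valid cell to its area-weighted percentile in {1/bins .. 1}.

    Cells are ranked by value; the cumulative area below a cell determines
    its bin, so each of the ``bins`` levels covers an equal share of the
    valid surface (to within one cell's area). The top bin is exactly 1
    (global maxima), the bottom 1/bins. Tied values share one percentile:
    the bin of the midpoint of their cumulative-area span (``midpoint``,
    default; a constant field maps to 0.5) or of its upper end (``max``).
    Masked cells stay masked.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if tie_rule not in ("midpoint", "max"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    if not field.same_geometry(areas):
        raise ValueError("field and area grids differ")
    v = field.values.ravel()
    a = areas.values.ravel()
    valid = np.isfinite(v)
    if not valid.any():
        raise ValueError("field has no valid cells")
    if np.any(a[valid] <= 0):
        raise ValueError("cell areas must be positive")

    vals = v[valid]
    wts = a[valid]
    order = np.argsort(vals, kind="stable")
    sv, sw = vals[order], wts[order]
    cum = np.cumsum(sw)
    total = cum[-1]
    # collapse ties: identical values share one cumulative-area span
    uniq, first_idx = np.unique(sv, return_index=True)
    run_end = np.append(first_idx[1:], sv.size) - 1
    hi = cum[run_end]
    lo = np.concatenate(([0.0], hi[:-1]))
    anchor = (lo + hi) / 2.0 if tie_rule == "midpoint" else hi
    frac = anchor / total
    pct_unique = np.ceil(frac * bins) / bins
    pct_unique = np.clip(pct_unique, 1.0 / bins, 1.0)
    inv = np.searchsorted(uniq, sv)
    pct_sorted = pct_unique[inv]
    pct = np.empty_like(vals)
    pct[order] = pct_sorted
    out = np.full(v.shape, np.nan)
    out[valid] = pct
    return field.with_values(out.reshape(field.shape), units="percentile")


def fuzzy_sum(components) -> np.ndarray | float:
    """Fuzzy sum 1 - prod(1 - x_k) over components in [0, 1].

    Commutative, bounded by 1, and never below its largest input; 0 is the
    identity and 1 the absorbing element. Components may be scalars or
    aligned arrays.
    """
    arrs = [np.asarray(c, dtype=float) for c in components]
    if not arrs:
        raise ValueError("fuzzy_sum needs at least one component")
    for c in arrs:
        fin = c[np.isfinite(c)] if c.ndim else (c if np.isfinite(c) else np.array([]))
        if np.any((np.asarray(fin) < 0) | (np.asarray(fin) > 1)):
            raise ValueError("fuzzy-sum components must lie in [0, 1]")
    prod = np.ones(np.broadcast_shapes(*(c.shape for c in arrs)))
    for c in arrs:
        prod = prod * (1.0 - c)
    out = 1.0 - prod
    return out if out.ndim else float(out)


def rescale_unit(values: pd.Series | np.ndarray) -> np.ndarray:
    """Min/max rescale to [0, 1]; a constant input maps to 0.5."""
    v = np.asarray(values, dtype=float)
    fin = np.isfinite(v)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        out = np.where(fin, 0.5, np.nan)
    else:
        out = (v - lo) / (hi - lo)
    return out


def ecological_sensitivity(
    p1: GeoGrid,
    p2: GeoGrid,
    scheme: BasinScheme,
    combine: str = "pairwise",
) -> pd.Series:
    """Per-basin ecological sensitivity E in (0, 1], max-normalized.

    Steps: basin-average each percentile-transformed input, average the two
    basin means, then divide by the global maximum so the most sensitive
    basin scores exactly 1. ``combine='pairwise'`` lets a basin covered by
    only one input use that input alone (the head-decline proxy only exists
    where groundwater is pumped); ``'strict'`` requires both.
    """
    if combine not in ("pairwise", "strict"):
        raise ValueError(f"unknown combine mode {combine!r}")
    m1 = basin_mean_intensive(p1, scheme)
    m2 = basin_mean_intensive(p2, scheme)
    both = pd.concat([m1, m2], axis=1)
    if combine == "pairwise":
        combined = both.mean(axis=1, skipna=True)
    else:
        combined = both.mean(axis=1, skipna=False)
    if not np.isfinite(combined).any():
        raise ValueError("no basin has valid ecological-sensitivity inputs")
    top = combined.max(skipna=True)
    if top <= 0:
        raise ValueError("global maximum combined sensitivity is not positive")
    E = combined / top
    E.name = "E"
    return E


def social_ecological_sensitivity(E, A) -> np.ndarray | float:
    """S = 1 - (1-E)(1-(1-A)): fuzzy sum of E and inverted adaptability.

    A = 1 (fully adaptable) leaves S = E; A = 0 forces S = 1 regardless of
    ecology. S >= max(E, 1-A) always.
    """
    E = np.asarray(E, dtype=float)
    A = np.asarray(A, dtype=float)
    for name, x in (("E", E), ("A", A)):
        fin = x[np.isfinite(x)]
        if np.any((fin < 0) | (fin > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = 1.0 - (1.0 - E) * (1.0 - (1.0 - A))
    return out if out.ndim else float(out)
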