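"""Basin freshwater indicators: stress, storage-trend, and combined status.

All functions are vectorized over basins and accept scalars or arrays.
Conventions: W = annual withdrawal (mm/yr), Q = annual streamflow (mm/yr),
trend = year-over-year total-water-storage change (mm/yr, negative =
drying). Basins with Q <= 0 are unscorable and come back NaN rather than
raising or dividing silently.
"""

from __future__ import annotations

import numpy as np


def _validate_wq(W, Q) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    W = np.asarray(W, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if np.any(W[np.isfinite(W)] < 0):
        raise ValueError("withdrawal W must be non-negative")
    scorable = np.isfinite(Q) & (Q > 0) & np.isfinite(W)
    return W, Q, scorable


def stress_ratio(W, Q):
    """Freshwater stress ratio W/Q; NaN where Q <= 0 (unscorable basin)."""
    W, Q, ok = _validate_wq(W, Q)
    out = np.full(np.broadcast(W, Q).shape, np.nan)
    out[ok] = (W / np.where(ok, Q, 1.0))[ok]
    return out if out.ndim else float(out)


def stress_indicator(W, Q, factor: float = 0.4):
    """Normalized freshwater stress F = min(W / (factor*Q), 1), in [0, 1]."""
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    r = np.asarray(stress_ratio(W, Q))
    out = np.minimum(r / factor, 1.0)
    return out if out.ndim else float(out)


def trend_indicator(trend, Q, factor: float = 0.4):
    """Normalized, flipped storage-trend indicator in [-1, 1].

    T = -1 * clamp(trend / (factor*Q), -1, 1), so drying (negative trend)
    maps to positive T, consistent in sign with the stress indicator.
    """
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    trend = np.asarray(trend, dtype=float)
    Q = np.asarray(Q, dtype=float)
    ok = np.isfinite(Q) & (Q > 0) & np.isfinite(trend)
    raw = trend / (factor * np.where(ok, Q, 1.0))
    out = np.where(ok, -np.clip(raw, -1.0, 1.0), np.nan)
    # avoid IEEE -0.0 leaking out of the flip
    out = out + 0.0
    return out if out.ndim else float(out)


def basin_status(F, T, earthquake=False):
    """Basin freshwater status B = max((F+T)/2, 0), in [0, 1].

    For earthquake-flagged basins the storage-trend observation is
    unreliable, so B falls back to the stress indicator alone: B = F.
    """
    F = np.asarray(F, dtype=float)
    T = np.asarray(T, dtype=float)
    eq = np.asarray(earthquake, dtype=bool)
    if np.any((F[np.isfinite(F)] < 0) | (F[np.isfinite(F)] > 1)):
        raise ValueError("F must lie in [0, 1]")
    finite_T = T[np.isfinite(T)]
    if np.any((finite_T < -1) | (finite_T > 1)):
        raise ValueError("T must lie in [-1, 1]")
    out = np.maximum((F + T) / 2.0, 0.0)
    out = np.where(eq, F, out)
    return out if out.ndim else float(out)


STRESS_LABELS = ("not stressed", "stressed", "highly stressed")
TREND_LABELS = ("drying", "no clear trend", "wetting")


def cooccurrence_class(
    ratio,
    trend,
    thresholds: tuple[float, float] = (0.10, 0.40),
    trend_threshold: float = 3.0,
    strict: bool = False,
):
    """Categorical stress x trend label (9 combinations), for mapping only.

    Stress categories use >= boundaries by default (a basin exactly at 0.40
    is "highly stressed"); ``strict=True`` switches to >. Trend boundaries
    are closed on the "no clear trend" side: |trend| <= trend_threshold is
    not a clear directional trend (the threshold is an observational error
    bar). The trend threshold is for categorization only and never enters
    the status indicator.
    """
    ratio = np.atleast_1d(np.asarray(ratio, dtype=float))
    trend = np.atleast_1d(np.asarray(trend, dtype=float))
    lo, hi = thresholds
    cmp = np.greater if strict else np.greater_equal
    s_idx = cmp(ratio, lo).astype(int) + cmp(ratio, hi).astype(int)
    t_idx = (trend >= -trend_threshold).astype(int) + (trend > trend_threshold).astype(int)
    ok = np.isfinite(ratio) & np.isfinite(trend)
    labels = np.array(
        [
            f"{STRESS_LABELS[s]} & {TREND_LABELS[t]}" if good else ""
            for s, t, good in zip(s_idx.ravel(), t_idx.ravel(), ok.ravel())
        ],
        dtype=object,
    ).reshape(ratio.shape)
    labels[~ok] = None
    return labels if labels.size > 1 else labels.ravel()[0]
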