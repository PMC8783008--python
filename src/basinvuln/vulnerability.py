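"""Vulnerability V = S * B and Head/Tail Breaks hotspot classification.

Vulnerability distributions across basins are heavy-tailed: most basins
score near zero and a few score very high. Head/Tail Breaks partitions such
data at the arithmetic mean and recursively re-partitions the head; with a
fixed depth of 3 this yields up to four classes (low, transitional, high,
very high). Hotspots are the basins in the high or very-high class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import VARIANTS, PipelineConfig
from .sensitivity import social_ecological_sensitivity

CLASS_NAMES = {0: "unscored", 1: "low", 2: "transitional", 3: "high", 4: "very high"}
HOTSPOT_CLASSES = (3, 4)


def vulnerability(S, B) -> np.ndarray | float:
    """V = S * B, the product of sensitivity and basin freshwater status."""
    S = np.asarray(S, dtype=float)
    B = np.asarray(B, dtype=float)
    for name, x in (("S", S), ("B", B)):
        fin = x[np.isfinite(x)]
        if np.any((fin < 0) | (fin > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = S * B
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HeadTailResult:
    """Break thresholds and integer class labels (1 = tail/lowest)."""

    breaks: tuple[float, ...]
    labels: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.breaks) + 1


def head_tail_breaks(values, iterations: int = 3, strict: bool = True) -> HeadTailResult:
    """Recursive mean partition of a heavy-tailed sample.

    Each iteration splits the current subset at its arithmetic mean; the
    head (values above the mean) is re-partitioned. Iteration stops early —
    with fewer resulting classes, never an error — when the head is empty,
    has fewer than two members, or has zero variance: the remaining members
    then form the top class. ``strict`` controls head membership (> mean,
    default) versus >= mean; the non-strict variant additionally stops when
    the head fails to shrink.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("head_tail_breaks requires at least one value")
    if not np.isfinite(v).all():
        raise ValueError("head_tail_breaks requires finite values")
    cmp = np.greater if strict else np.greater_equal
    breaks: list[float] = []
    current = v
    for _ in range(iterations):
        m = float(current.mean())
        head = current[cmp(current, m)]
        if head.size == 0 or head.size == current.size:
            break
        breaks.append(m)
        if head.size < 2 or float(head.var()) == 0.0:
            break
        current = head
    labels = np.ones(v.size, dtype=int)
    for b in breaks:
        labels += cmp(v, b).astype(int)
    return HeadTailResult(breaks=tuple(breaks), labels=labels)


def classify_vulnerability(
    table: pd.DataFrame,
    variant: str = "social-ecological",
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Classify basins into vulnerability classes for one variant.

    ``table`` must carry per-basin columns B, E, A. The sensitivity entering
    V depends on the variant: the fuzzy sum of E and 1-A (social-ecological),
    1-A alone (social), or E alone (ecological). Returns a frame indexed by
    basin with columns S_variant, V, vclass (0 = unscorable), class_label,
    hotspot, variant. Zero-V basins are included in the break computation by
    default (``config.include_zero_v``); excluded, they are still labelled
    class 1.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    config = config or PipelineConfig()
    missing = {"B", "E", "A"} - set(table.columns)
    if missing:
        raise KeyError(f"table lacks columns {sorted(missing)}")
    B = table["B"].to_numpy(dtype=float)
    E = table["E"].to_numpy(dtype=float)
    A = table["A"].to_numpy(dtype=float)
    if variant == "social":
        S = 1.0 - A
    elif variant == "ecological":
        S = E.copy()
    else:
        S = np.asarray(social_ecological_sensitivity(E, A))
    V = S * B

    scorable = np.isfinite(V)
    vclass = np.zeros(V.size, dtype=int)
    if scorable.any():
        vs = V[scorable]
        if config.include_zero_v:
            fit = vs
        else:
            fit = vs[vs > 0]
        if fit.size == 0:
            vclass[scorable] = 1
        else:
            res = head_tail_breaks(
                fit, iterations=config.htb_iterations, strict=config.htb_strict
            )
            cmp = np.greater if config.htb_strict else np.greater_equal
            labels = np.ones(vs.size, dtype=int)
            for b in res.breaks:
                labels += cmp(vs, b).astype(int)
            vclass[scorable] = labels
    out = pd.DataFrame(
        {
            "S_variant": S,
            "V": V,
            "vclass": vclass,
            "class_label": [CLASS_NAMES[c] for c in vclass],
            "hotspot": np.isin(vclass, HOTSPOT_CLASSES),
            "variant": variant,
        },
        index=table.index,
    )
    return out
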