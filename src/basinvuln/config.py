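"""Pipeline configuration: every threshold, toggle and seed in one place."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace
from typing import Any, Iterator


VARIANTS = ("social-ecological", "social", "ecological")


@dataclass(frozen=True)
class PipelineConfig:
    """All methodological knobs of the vulnerability pipeline.

    Attributes
    ----------
    norm_factor : float
        Fraction of annual streamflow used to normalize both the stress and
        the storage-trend indicator (0.4 is the conventional high-stress
        threshold in the water-scarcity literature).
    stress_thresholds : (float, float)
        W/Q cut points for the stressed / highly-stressed categories.
    stress_strict : bool
        False: a basin exactly at a threshold is in the higher category
        (>= semantics); True: strict > semantics.
    trend_threshold : float
        |trend| (mm/yr) below which a storage trend counts as "no clear
        trend" in the categorical co-occurrence scheme only; it never enters
        the status indicator.
    percentile_bins : int
        Granularity of the area-weighted percentile transform.
    tie_rule : str
        'midpoint' (ties get the percentile of the midpoint of their
        cumulative-area span) or 'max' (upper end of the span).
    eco_combine : str
        'pairwise': a basin missing one ecological input uses the other
        alone; 'strict': both inputs required.
    adaptive_rescale : bool
        Rescale adaptive capacity to [0,1] by its global min/max before
        inversion (needed for datasets on other native scales).
    include_zero_v : bool
        Include zero-vulnerability basins when computing class breaks.
    htb_iterations : int
        Head/Tail Breaks depth (3 -> up to 4 classes).
    htb_strict : bool
        True: head membership is v > mean; False: v >= mean.
    variant : str
        Which sensitivity enters vulnerability: 'social-ecological'
        (fuzzy sum of E and 1-A), 'social' (1-A alone), 'ecological'
        (E alone).
    """

    norm_factor: float = 0.4
    stress_thresholds: tuple[float, float] = (0.10, 0.40)
    stress_strict: bool = False
    trend_threshold: float = 3.0
    percentile_bins: int = 100
    tie_rule: str = "midpoint"
    eco_combine: str = "pairwise"
    adaptive_rescale: bool = False
    include_zero_v: bool = True
    htb_iterations: int = 3
    htb_strict: bool = True
    variant: str = "social-ecological"

    def __post_init__(self) -> None:
        if self.norm_factor <= 0:
            raise ValueError("norm_factor must be positive")
        lo, hi = self.stress_thresholds
        if not 0 <= lo < hi:
            raise ValueError("stress thresholds must satisfy 0 <= low < high")
        if self.trend_threshold < 0:
            raise ValueError("trend_threshold must be >= 0")
        if self.percentile_bins < 1:
            raise ValueError("percentile_bins must be >= 1")
        if self.tie_rule not in ("midpoint", "max"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")
        if self.eco_combine not in ("pairwise", "strict"):
            raise ValueError(f"unknown eco_combine {self.eco_combine!r}")
        if self.htb_iterations < 1:
            raise ValueError("htb_iterations must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def config_grid(base: PipelineConfig | None = None, **axes: list) -> Iterator[PipelineConfig]:
    """Yield configs over the Cartesian product of the given axes.

    ``config_grid(stress_strict=[False, True], norm_factor=[0.2, 0.4, 0.8])``
    yields six configurations around ``base`` (default config if omitted).
    """
    base = base or PipelineConfig()
    names = list(axes)
    for combo in itertools.product(*(axes[n] for n in names)):
        yield base.replace(**dict(zip(names, combo)))
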