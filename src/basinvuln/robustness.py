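"""Monte-Carlo uncertainty propagation and methodological config sweeps.

Two perturbation modes mirror the two uncertainty analyses: spatially
*uniform* (one multiplicative factor per input per realization, a uniform
over/under-estimation of that dataset) and spatially *variable* (a
correlated per-cell factor field with the same uniform marginal). Each
realization re-runs the full pipeline; the report tracks, per basin, the
fraction of realizations in which it stays at least "transitional", and
summarizes what fraction of the baseline transitional-plus-hotspot basins
keep that standing in a majority of realizations.

Per-realization randomness is counter-based: the generator for realization
r of input k is seeded by (master seed, r, k), so realizations are
order-independent and individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .pipeline import run_pipeline
from .synthetic import (
    ANALYSIS_FIELDS,
    SyntheticWorld,
    _correlated_standard_field,
)

#: factors are floored here so multiplicative noise can never flip a sign
_FACTOR_FLOOR = 1e-9


@dataclass(frozen=True)
class PerturbationSpec:
    """How to perturb the analysis inputs.

    ``magnitudes`` is either one relative magnitude m (factors drawn from
    U[1-m, 1+m] for every input) or a mapping input-name -> m. In spatial
    mode the factor field is a correlated Gaussian field pushed through its
    CDF, so the per-cell marginal is the same U[1-m, 1+m].
    """

    mode: str = "uniform"
    magnitudes: float | Mapping[str, float] = 0.2
    corr_len: float = 5.0
    n_realizations: int = 100
    seed: int = 0
    inputs: tuple[str, ...] = ANALYSIS_FIELDS

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "spatial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        for name in self.inputs:
            if self.magnitude_for(name) < 0:
                raise ValueError(f"magnitude for {name} must be >= 0")

    def magnitude_for(self, name: str) -> float:
        if isinstance(self.magnitudes, Mapping):
            return float(self.magnitudes.get(name, 0.0))
        return float(self.magnitudes)


@dataclass(frozen=True)
class RobustnessReport:
    """Per-basin class-retention fractions and their summary."""

    retention: pd.Series  # fraction of realizations at class >= transitional
    baseline_vclass: pd.Series
    summary_fraction: float  # of baseline >=transitional basins retained >50%
    n_realizations: int
    n_factor_floor_events: int = 0


def perturb_world(
    world: SyntheticWorld, spec: PerturbationSpec, realization_index: int
) -> tuple[SyntheticWorld, int]:
    """One perturbed copy of the world, deterministic in (seed, index).

    Returns the perturbed world and the number of cells/inputs where a
    factor had to be floored to keep the input's sign (only possible for
    magnitudes >= 1).
    """
    new_fields = {}
    floor_events = 0
    for k, name in enumerate(spec.inputs):
        if name not in world.fields:
            continue
        m = spec.magnitude_for(name)
        grid = world.fields[name]
        if m == 0:
            new_fields[name] = grid
            continue
        rng = np.random.default_rng([spec.seed, realization_index, k])
        if spec.mode == "uniform":
            factor = 1.0 + m * (2.0 * rng.random() - 1.0)
            factor = max(factor, _FACTOR_FLOOR)
            if factor == _FACTOR_FLOOR:
                floor_events += 1
            values = grid.values * factor
        else:
            z = _correlated_standard_field(rng, grid.shape, spec.corr_len)
            u = stats.norm.cdf(z)
            factors = 1.0 + m * (2.0 * u - 1.0)
            floored = factors < _FACTOR_FLOOR
            floor_events += int(floored.sum())
            factors = np.maximum(factors, _FACTOR_FLOOR)
            values = grid.values * factors
        if name == "adaptive_capacity":
            values = np.clip(values, 0.0, 1.0)
        new_fields[name] = grid.with_values(values)
    return world.with_fields(new_fields), floor_events


def run_realizations(
    world: SyntheticWorld,
    spec: PerturbationSpec,
    config: PipelineConfig | None = None,
) -> RobustnessReport:
    """Propagate input uncertainty through the full pipeline.

    Re-classifies every realization and accumulates, per basin, the fraction
    of realizations in which the basin lands at class >= 2 (transitional or
    hotspot). The summary is the fraction of baseline transitional/hotspot
    basins whose retention fraction exceeds 0.5.
    """
    config = config or PipelineConfig()
    baseline = run_pipeline(world, config)
    at_least = np.zeros(len(baseline), dtype=float)
    floor_events = 0
    for r in range(spec.n_realizations):
        perturbed, ev = perturb_world(world, spec, r)
        floor_events += ev
        try:
            result = run_pipeline(perturbed, config)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"pipeline failed in realization {r}") from exc
        at_least += (result["vclass"].to_numpy() >= 2).astype(float)
    retention = pd.Series(
        at_least / spec.n_realizations, index=baseline.index, name="retention"
    )
    base_sel = baseline["vclass"] >= 2
    if base_sel.any():
        summary = float((retention[base_sel] > 0.5).mean())
    else:
        summary = float("nan")
    return RobustnessReport(
        retention=retention,
        baseline_vclass=baseline["vclass"],
        summary_fraction=summary,
        n_realizations=spec.n_realizations,
        n_factor_floor_events=floor_events,
    )


@dataclass(frozen=True)
class SweepResult:
    """Per-config class labels, pairwise agreement, and the consistent set."""

    labels: pd.DataFrame  # basins x configs, integer vclass
    agreement: pd.DataFrame  # configs x configs, fraction of equal labels
    consistent_ids: tuple[int, ...]  # >= transitional in a majority of configs
    configs: tuple[PipelineConfig, ...] = field(repr=False, default=())


def config_sweep(
    world: SyntheticWorld, configs: Sequence[PipelineConfig]
) -> SweepResult:
    """Re-classify the world under alternative methodological configs."""
    configs = tuple(configs)
    if not configs:
        raise ValueError("config_sweep needs at least one configuration")
    cols = {}
    for i, cfg in enumerate(configs):
        cols[f"config_{i}"] = run_pipeline(world, cfg)["vclass"]
    labels = pd.DataFrame(cols)
    n = len(configs)
    agree = np.ones((n, n))
    arr = labels.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            agree[i, j] = agree[j, i] = float((arr[:, i] == arr[:, j]).mean())
    agreement = pd.DataFrame(agree, index=labels.columns, columns=labels.columns)
    majority = (arr >= 2).mean(axis=1) > 0.5
    consistent = tuple(int(b) for b in labels.index[majority])
    return SweepResult(
        labels=labels, agreement=agreement, consistent_ids=consistent,
        configs=configs,
    )
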