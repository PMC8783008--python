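# Methods

This note documents the models and procedures implemented in `basinvuln`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic test worlds do and do not establish about real data.

## Geospatial conventions

All gridded inputs share one regular lat-lon raster (default 0.5°). Cell
areas use the closed-form authalic-sphere formula
`A(φ) = R² Δλ (sin φ_top − sin φ_bottom)` with R = 6371.0088 km. Relative
to ellipsoidal areas the spherical formula deviates by < 0.3% at any
latitude, which is immaterial for area *weights*; in exchange it is exact,
closed-form and dependency-free. Grid registration places cell centers at
half-resolution offsets (a global 0.5° grid runs 89.75…−89.75 ×
−179.75…179.75); cell ownership for point overlays is half-open with west
and south edges inclusive, so every point belongs to at most one cell.

Each cell belongs wholly to one basin (no sub-cell apportioning) — the
simplest consistent reading once all inputs are harmonized to a common
grid. Missing cells are excluded from both numerator and denominator of
intensive means, never zero-filled; a basin with no valid cell is missing,
not zero. Extensive fields are summed within basins, so basin sums plus the
masked-cell total conserve the global total exactly.

## Indicator construction

Stress `F = min(W/(f·Q), 1)` and trend `T = −clamp((dTWS/dt)/(f·Q), −1, 1)`
share the normalization factor `f = 0.4` (the conventional "high stress"
fraction of annual streamflow; configurable). Both are bounded at magnitude
1 so a single extreme input cannot dominate the composite. The trend is
flipped so drying is positive, aligning its sign convention with stress.
Basin status `B = max((F+T)/2, 0)` floors at zero because strong wetting
can otherwise produce negative status. Basins flagged as
earthquake-affected (storage-trend observations corrupted by mass
redistribution) use `B = F`; the implementation keeps this fallback exactly
invariant to the trend input, which the tests assert.

Stress categories use ≥ boundaries (a basin at exactly W/Q = 0.10 is
stressed; at 0.40, highly stressed), with a strict-inequality toggle. The
±3 mm yr⁻¹ "clear trend" threshold reflects the error level of
satellite-observed storage trends and is used **only** for the categorical
stress × trend labels; it never enters B, enforced by keeping it out of the
indicator code paths. Trend categories are closed on the "no clear trend"
side: a trend exactly at the error bar is not clear evidence of direction.
Basins with Q ≤ 0 (possible in synthetic deserts) are unscorable: they are
excluded from classification and reported, since stress is undefined
without streamflow.

## Sensitivity indicators

The two ecological inputs have incommensurable units, so each is converted
to an area-weighted percentile field: cells are ranked by value and the
cumulative valid area is cut into 100 equal-area bins (bin k → k/100), so
every percentile level covers the same share of the land surface to within
one cell's area. Ties share the percentile of the midpoint of their
cumulative-area span; this preserves the equal-area semantics and gives a
defined result for constant fields (0.5). An upper-end tie rule is provided
as a sweep axis. The bin count (100) is configurable.

Basin ecological sensitivity E averages the two basin-mean percentile
fields and normalizes by the global maximum basin value, so the most
sensitive basin scores exactly 1. The head-decline input exists only where
groundwater is pumped, so by default a basin covered by only one input uses
that input alone (pairwise-available averaging); a strict-intersection
toggle is provided.

Adaptive capacity A ∈ [0,1] is inverted to 1−A ("sensitivity of society")
and combined with E by the fuzzy sum `S = 1 − (1−E)(1−(1−A))`. The fuzzy
sum is commutative, bounded by 1, never below its largest input, and
weight-free — the reason to prefer it over a weighted average here. An
optional min/max rescaling of A to [0,1] is available (off by default: the
synthetic generator already emits A on the unit interval; it exists for
external datasets on other native scales).

## Vulnerability and classification

`V = S·B` per basin. The V distribution across basins is heavy-tailed, so
classification uses Head/Tail Breaks: split at the arithmetic mean, keep
the head (values strictly above the mean), and recurse. Depth is fixed at
three iterations — four classes (low, transitional, high, very high) — for
consistency across the social, ecological, and combined variants, rather
than a skewness stopping rule. Degenerate heads (empty, singleton, or
zero-variance) stop the recursion early and simply yield fewer classes,
never an error. Strict head membership (v > mean) guarantees the head
shrinks. Zero-vulnerability basins are included in break computation by
default — they are ordinary members of the low class — with an exclusion
toggle because the choice is genuinely open; both are sweep axes.

Hotspots are classes 3–4. The social variant replaces S with 1−A, the
ecological variant with E; both reuse the identical classification
procedure.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes, not
any particular real dataset:

- **Basins**: seeded region growing (multi-source Dijkstra with
  exponential random edge weights) over the unmasked grid — contiguous,
  compact, irregular regions without hydrological routing. A configurable
  fraction of northern rows is masked, emulating excluded data-sparse
  basins.
- **Fields**: Gaussian random fields approximated by kernel-smoothed white
  noise (cheap, with a controllable correlation length; length 0 gives
  independent cells), pushed through marginal transforms. Defaults:
  streamflow lognormal (median 200 mm yr⁻¹, σ = 1), withdrawal lognormal
  (median 20 mm yr⁻¹, σ = 1.5) so W/Q centres near 0.1 and exceeds 1 in a
  small tail, as in real basin populations; storage trends Gaussian
  (sd 8 mm yr⁻¹, smooth), matching the magnitude of satellite-derived
  trends; adaptive capacity Beta(2,2) through a normal copula; heavy-tailed
  lognormal sensitivity proxies, the head-decline proxy with 60% coverage;
  lognormal extensive fields (population, crop production, GDP) in abstract
  units.
- **Nations**: an independent region-growing tessellation, so basins
  straddle borders and transboundary basins arise naturally; IWRM scores
  uniform on [0, 100].
- **Planted hotspots**: a planted basin's cell stress ratios are floored at
  the global median ratio and then multiplied by the stress multiplier (by
  raising W). Flooring first makes the planted ground truth hold by
  construction — a pure multiplicative bump on a basin that happens to sit
  in the far low tail of the heavy-tailed W/Q distribution would not
  produce a stressed basin, which would make "planted hotspot" an unreliable
  label rather than a ground truth. The trend offset, adaptability ceiling,
  and sensitivity floor (a global quantile of each ecological field) are
  applied directly.

Everything derives from one integer seed through named sub-streams, so a
fixed seed reproduces the world bitwise. What passing tests on these worlds
show: the machinery (aggregation, transforms, classification, perturbation)
is correct and recovers known structure. What they do not show: fidelity of
any real dataset's marginals, spatial covariance between real inputs (e.g.
withdrawal concentrating where adaptive capacity is high), sub-grid
variability, or real-world magnitudes of exposure — those require the real
rasters.

## Uncertainty, sensitivity, and IWRM

Perturbations are multiplicative with factors uniform on [1−m, 1+m]:
spatially *uniform* draws one factor per input per realization (a uniform
over/under-estimation of a dataset, preserving within-field rank order);
spatially *variable* uses a correlated Gaussian field pushed through its
CDF so the per-cell marginal is the same uniform. The default magnitude is
±20%, a round, conservative figure for global gridded hydrological and
socio-economic data; the CLI refuses to default it silently. Perturbed A is
re-clipped to [0,1]; factors are floored at a tiny positive value so signs
never flip (only reachable for m ≥ 1, and counted when it happens).
Realization r of input k is seeded by (master seed, r, k), so realizations
are order-independent and individually reproducible. The report tracks the
per-basin fraction of realizations at class ≥ transitional, summarized as
the fraction of baseline transitional-plus-hotspot basins retained in more
than half the realizations. Desk-scale defaults (hundreds to thousands of
realizations on 50–200-basin worlds) keep a full analysis in seconds to
minutes; the retention summary is stable to ±0.05 between 10³ and 10⁴
realizations on a fixed small world.

The configuration sweep re-runs the pipeline over a user-defined grid of
methodological choices (stress boundary strictness, normalization factor,
percentile bins, tie rule, zero-V inclusion, adaptive-capacity rescaling,
head-membership strictness) and reports per-config labels, pairwise
agreement, and the set of basins at least transitional in a majority of
configurations.

Basin IWRM scores are overlap-area-weighted means of national scores (a
population-weighted alternative would need a population raster join; the
area-weighted form matches how every other intensive property is basin
aggregated here). Quadrant splits for the IWRM-vulnerability comparison are
configuration values — qualitative in nature — defaulting to 50 on the
0–100 IWRM axis and the hotspot flag on the vulnerability axis.

## Numerical notes and limitations

- Aggregations use `bincount` accumulation; equivalence with loop-based
  oracles is tested at 1e-12 relative tolerance.
- Percentile bin assignment uses `ceil` of the cumulative-area fraction;
  exact bin occupancy can deviate from perfect equality by at most one
  cell's area around each bin boundary.
- Head/Tail Breaks with < 2 distinct values yields a single class;
  classification never fails on degenerate inputs.
- The pipeline carries basins, not flow routing: upstream-downstream water
  sharing, arid-zone special treatment, and virtual-water effects are out
  of scope by design.
- GeoJSON/NetCDF output targets interchange, not cartography; polygons are
  dissolved cell unions, not smoothed basin outlines.
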