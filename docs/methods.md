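# Methods

This note documents the models, conventions, and numerical choices behind
`firesmoke`, and what the synthetic scenarios do and do not establish about
real data.

## Fire attribution by run differencing

Fire-attributable PM2.5 is the cell-day difference between a chemical-
transport-model run with all emission sources and a paired run with fire
sources removed: fire = C_all − C_nofire. Because atmospheric chemistry and
transport are nonlinear, the two runs are not strictly nested and the
difference can be slightly negative in places. Negative differences are
**retained by default** — clipping them would silently destroy the exact
conservation fire + C_nofire = C_all, which downstream consistency checks
rely on. An optional `clip_negative` flag sets them to zero and logs the
count for users who prefer a physically signed field.

Daily values follow the midnight-to-midnight convention in **local** time:
`daily_from_hourly` shifts hourly model output by an integer UTC offset
(−8 for Pacific Standard Time), averages each complete 24-hour local day,
and drops (and logs) partial first/last days.

## The centroid rule and its edge cases

A grid cell contributes to an administrative unit exactly when its centroid
lies within the unit polygon. Coordinates are planar projected values; no
geodesic computation is attempted, which is appropriate for projected model
grids (12-km cells in the replication configuration). Conventions the rule
needs but that are underdetermined in the field's practice:

- A centroid exactly on a shared boundary is *covered* by every abutting
  polygon; it is assigned to the unit whose `unit_id` sorts first
  lexicographically, with a warning. This is deterministic and independent
  of input order; it is a convention, not an empirical claim.
- Cells covered by no polygon stay "unassigned" and never enter unit
  statistics (model grids typically extend beyond the study region).
- Units that capture no centroid are flagged "empty" and propagate as
  missing data (not zeros) through every downstream table — the realistic
  case being an administrative unit smaller than one grid cell.
- Ring orientation is ignored; holes are honoured.

Unit daily means are unweighted arithmetic means over member cells, so
aggregation commutes: the period mean of the unit daily series equals the
mean over all member cell-days.

## Summaries, exposure classes

Annual and period summaries report the mean and **population** standard
deviation (divide by n, `ddof=0`) of the available daily values; `ddof` is
configurable since published tables rarely state the convention. Annual
means use all available days of a unit-year by default (`min_coverage=0`),
with an optional minimum-coverage fraction.

Percent attributable is 100 · mean(fire) / mean(all) over a common set of
days and cells, computed at full precision and rounded only for
presentation (one decimal, matching the published tables).

Exposure classes bin annual-mean fire-PM2.5 at the quartile breaks (25th/
50th/75th percentiles, linear interpolation between order statistics) of
the pooled unit-year annual means. Intervals are lower-open/upper-closed:
a value exactly equal to a break belongs to the lower class, and 0 belongs
to class 1. Negative annual means (possible with clipping off) classify as
class 1 with a warning. The replication configuration can instead fix the
breaks at the published 0.34/0.56/0.86 μg/m³. When classes must be reduced
to one per unit over a multi-year period (for the at-risk join), the
pipeline classifies the unit's period mean against the pooled-unit-year
breaks; the alternative (modal annual class) was rejected as harder to
interpret and not better determined by the source material.

## Smokewaves

A smokewave is a maximal run of consecutive calendar days whose daily
fire-PM2.5 **strictly exceeds** the threshold (default 35 μg/m³, the 24-h
NAAQS level), lasting at least `min_consecutive_days` (default 3, reading
"more than two consecutive days" literally; the adjacent heatwave
literature often uses 2, so both knobs are exposed). Date gaps split runs;
missing days count as non-exceedance. Episodes carry start, end, length and
peak; an episode spanning a year boundary is counted once, in its start
year. Period totals are sums of yearly counts.

One property worth stating precisely: the episode *count* is monotone
non-increasing in `min_consecutive_days`, but **not** in the threshold — a
higher threshold can split one long run into two shorter runs that both
still qualify. The monotone quantity in the threshold is the number of
episode-covered days, and that is what the property tests assert.

## Populations at risk

Each unit's counts are attributed wholly to the unit's exposure class — a
deliberate unit-level (ecological) design with no within-unit
apportionment. Class rows plus a "missing" row (units without model data)
sum to the total row by construction. `fraction_above` reports sums and
percentages of any column in classes at or above a cut, at full precision;
`at_risk_from_class_sums` accepts pre-aggregated published tables whose
printed totals carry their own rounding and must be preserved as the
denominator. A helper implements proportional allocation of pooled
small-unit counts (e.g. births published only as an "unidentified
counties" total) by total population.

## Model evaluation

Monitors are matched to the cell whose half-open rectangle
[left, right) × [bottom, top) contains them, so interior points map to
exactly one cell; points on the far right/top edge of the grid fall
outside and are dropped with a logged warning. Monitor-days split into
"wildfire-impacted" (predicted fire carbon strictly > 0.34 μg/m³) and
"little or no" strata — the same number as the first exposure-class break
in the replication configuration, but an independent knob. Per stratum and
year the summary reports N, mean observed, mean predicted and the bias
predicted − observed at full precision. The evaluation deliberately targets
PM2.5 carbon (organic + elemental), the species that dominates smoke
plumes, not total PM2.5; days with an observation but no prediction (or
vice versa) are excluded pairwise and logged. No attempt is made to
evaluate days where smoke is present but the model predicts zero impact —
without a prediction there is no stratum to place them in.

## Synthetic scenarios

The generator emulates the statistical shape of the real inputs, not their
physics:

- **Background (no-fire) field**: seasonal sinusoid (winter maximum)
  around a mean level, times mean-one lognormal noise whose log is AR(1)
  in time (lag-1 autocorrelation ρ) with spatially Gaussian-smoothed
  innovations, re-standardized to unit marginal variance cell by cell
  (exactly, including filter edge effects). The lognormal transform
  attenuates the field's lag-1 autocorrelation slightly below ρ
  (≈0.49 for ρ=0.5, σ=0.3), which the tests account for. Defaults:
  mean 3.7 μg/m³, amplitude 1.2, ρ=0.5, σ=0.3, smoothing 2 cells.
- **Fire plumes**: isotropic Gaussian blobs (σ in cells) with linear
  advection and a trapezoidal rise-plateau-decay temporal profile,
  additive across events — the simplest shape giving sharp multi-day
  peaks over many near-zero days. It is a stand-in, not a dispersion
  model. The default season (per year: two events of peak 200 μg/m³,
  σ=3 cells, 10 days; one of peak 120, σ=2, 6 days on a 20×20 grid) was
  sized analytically so the injected fire mass is ≈25% of the total
  period mean — the regime of a high-fire multi-year period — and so unit
  series show isolated multi-day peaks above 35 μg/m³ while ≥80% of
  unit-days stay below 1 μg/m³.
- **Quantization**: generated concentrations are rounded to multiples of
  2⁻²⁰ μg/m³ (≈10⁻⁶). Sums and differences of such values are exact in
  IEEE double arithmetic at these magnitudes, so composing
  all = background + fire and then differencing recovers the stored truth
  bit for bit — making "exact recovery" a meaningful oracle rather than a
  tolerance test.
- **Units**: a rectangular tiling of the grid extent (default 2×4),
  optionally plus one sub-cell unit avoiding all centroids.
- **Monitors**: observations = carbon_fraction × true total PM2.5 ×
  per-year bias factor × mean-one lognormal noise, on a daily, 1-in-3 or
  1-in-6 staggered schedule; noise-free, bias-free predictions are stored
  alongside, so the stratified summary's bias estimate can be checked
  against (1 − bias) × mean prediction.
- **Determinism**: one stream per generator, spawned from the master seed,
  so changing the monitor count never perturbs the fields.

What passing tests on these scenarios shows: the pipeline arithmetic —
differencing, aggregation, classification, episode detection, tabulation,
stratified bias estimation — is correct and deterministic. What they do
not show: anything about emission inventories, plume physics, chemistry,
or how faithfully a real model reproduces real monitors; the synthetic
fields have none of the spatial heterogeneity of terrain-driven dispersion
and their noise is exactly lognormal, which real residuals are not.

## Scale and defaults

The default scenario (20×20 cells, 2 years, 8+1 units, 10 monitors) keeps
the full test suite in seconds while being large enough for every code
path — empty units, year-boundary episodes, staggered monitor cadences —
to occur. The multi-year shape checks use a 7-year run of the same grid.
The published California tables shipped in `firesmoke.reference` cover the
parts of the original analysis that are exactly reproducible from print:
derived percentages, sums and biases; the statewide gridded magnitudes
themselves would require the original multi-terabyte paired model runs.

## Known limitations

- No map reprojection: all geometries must already be in the grid's
  planar coordinate system.
- No population-weighted (dasymetric) cell-to-unit apportionment; the
  centroid rule is all-or-nothing per cell.
- Speciation is limited to a single carbon-fraction proxy for evaluation.
- At-risk tables link counts to exposure classes cross-sectionally; no
  temporal linkage of events to exposure windows is attempted.
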