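# Methods

This note records the models and procedures the package implements, the
assumptions behind them, the parameter defaults and why they were chosen,
what the synthetic data does and does not emulate, and the numerical
choices that make results deterministic.

## Raster model

All gridded quantities are `Layer`s: a dense float array plus an explicit
boolean validity mask on a `GridSpec` (rows × cols, cell size, outer-corner
origin, free-text CRS id). Grids are row-major and north-up; cell (r, c)
covers the half-open box
`[origin_x + c·s, origin_x + (c+1)·s) × (origin_y − (r+1)·s, origin_y − r·s]`.
Two layers interoperate only when all six spec fields are equal; every
cellwise operation asserts this and names the first differing field.

Resolution changes are integer block aggregations only, and always from
finer to coarser. Extensive quantities (areas, tonnes, impact totals)
aggregate with `sum`, which conserves mass exactly up to float
re-association (tested at 1e-9 relative); intensive quantities (per-tonne
intensities, richness when coarsening) use `mean` over the valid children.
A coarse cell with no valid children is invalid. There is no reprojection
engine: synthetic grids are abstract equal-area, and real-data
reprojection/format conversion (e.g. from GeoTIFF) is a preprocessing
requirement outside the package. The native file format is a plain-text
grid chosen for dependency-free, diff-able fixtures.

## Impact layers

For the four mass-based indicators (GHG, LND, Nit, Pho) the per-cell
impact is `intensity × dry-weight production`, where dry weight is fresh
production times a crop-specific dry-matter fraction in (0, 1]. The
shipped fractions (wheat 0.87, sugarcane 0.27, sugar beet 0.21, oil palm
0.53, cocoa 0.90) are typical literature values intended as overridable
configuration, not calibrated constants; every real analysis should set
its own. Cocoa carries only GHG and LND because intensity data for the
other indicators do not exist for it; the layer set for a crop is
restricted to its `available_indicators` and a missing configured
intensity is a hard configuration error.

Water debt (WAT) is different in kind: a ratio of annual crop water
footprint to renewable water, in years. A value of one means use exactly
equals renewal, so the unsustainable set is defined by a *strict*
comparison — cells with WD ≤ 1 (including exactly 1.0) are removed before
any normalization — and the debt surface is used directly, never
multiplied by production, because its unit is years, not an impact per
tonne. Whether a production-weighted WAT variant is wanted is left to the
caller (the filter and the multiplication are separate operations), but
the shipped pipeline never multiplies.

Zeros in impact layers are converted to missing *after* the
multiplication: zero cells in the source surfaces sit over water bodies
(absence of measurement, not zero impact), and multiplying first lets
zero-production cells drop out in the same pass. Sugar is the union
overlay of sugarcane and sugar beet: cells occupied by both are summed,
cells occupied by one pass through, matching the fact that the two crops
rarely co-occur but traded sugar does not distinguish them.

## Normalization, classes, hotspots

Indicators live on incomparable scales, so each impact layer is min–max
normalized to [0, 1] over its own valid cells, per crop × per indicator,
globally (not per country) — that is the scope that makes the composite
maps comparable across indicators. A constant layer normalizes to all
zeros (zero spread puts every cell at the minimum); this degenerate rule
is documented rather than an error because constant layers arise in tiny
fixtures.

Class maps use the 0.10 and 0.90 empirical quantiles of the valid values
with *strict* comparisons: low `< q10`, high `> q90`, medium otherwise.
Quantiles are linear interpolation of order statistics (numpy's `linear`
method), fixed so results are reproducible. Strictness means a constant
layer is all medium and ties at a threshold fall to medium. The published
class bounds ("<10 %, 11–89 %, >90 %") leave the 10–11 and 89–90 bands
unspecified and do not say value scale or rank scale; quantile thresholds
with strict inequalities are the default reading, and an absolute
value-scale mode (`mode="value"`) is available for normalized layers.

Hotspot masks flag exactly `ceil(0.10 · n_valid)` cells, the highest by
value, with ties broken by row-major cell order so the count is exact and
the result deterministic. The dominant-indicator composite takes, per
cell, the indicator with the largest normalized value among those valid
there, ties resolved by the fixed canonical order GHG < LND < Nit < Pho <
WAT; the total composite sums normalized values over valid indicators.
Bivariate maps bin each axis independently into quantile classes (default
3×3) over that axis's valid cells; a cell is classed only where both
inputs are valid. No randomness exists anywhere in this stage.

## Origin tracing

Bilateral flow matrices overstate trade partners as producers because of
re-exports. The correction treats each country's total supply
`s_c = P_c + Σ_e T[e,c]` as a mixing pool: exports inherit the pool's
origin composition proportionally. The origin mass `X[o,c]` of producer o
inside c's supply satisfies

    X[o,c] = P_c · 1[o=c] + Σ_e (X[o,e] / s_e) · T[e,c]

and is solved by fixed-point iteration from `X = diag(P)`, stopping when
the largest absolute change is below 1e-9 tonnes (cap 10,000 iterations;
exceeding the cap is an error that reports the residual). The iteration
converges geometrically because the supply-normalised flow matrix is
sub-stochastic whenever any country consumes. Attributed consumption is
the supply mix scaled by apparent consumption `s_c − exports_c`. Tests
check the fixed point against two independent references: explicit
path-enumeration with proportional splitting on random acyclic networks,
and the direct linear solve `X = diag(P)(I − F)^{-1}`; a two-country
cycle is checked against its geometric-series closed form.

Mirror-reported trade data routinely contain countries whose recorded
exports exceed any possible supply; these are handled by scaling the
offending country's export flows down proportionally (repeated until
consistent), with a warning recorded in the result rather than a failure.

Window averaging divides by the full window length, counting absent
records as zero — an 11-year mean for 2003–2013 regardless of how many
years a dyad actually traded. Sugar-crop items are folded into a single
"sugar" item before tracing because traded sugar products rarely identify
the source crop. Supplier tables include the consumer itself (domestic
production) as an origin; the major-supplier cut keeps consumption shares
≥ 5 % (inclusive boundary), sorted descending with country-name
tie-breaks. Product-to-primary-crop weight conversion is a configuration
factor with default 1 (e.g. chocolate:cocoa treated 1:1).

## Country profiles and species overlap

Country masks assign every valid cell wholly to one country — no
fractional border cells, an accepted approximation at the 5–30 km cell
sizes this pipeline targets. Totals are zonal sums of normalized layers;
per-tonne values divide by the zonal production sum and are NaN where a
country produces nothing. Zonal sums are additive over a partition, which
is the tested invariant.

Species overlap is cell-count based: a cell is "producing" iff the crop's
physical area is valid and strictly greater than `min_area` (default 0
ha — any positive area counts), and a species' overlap fraction is
producing-cells-in-range / range-cells. On an equal-area grid this equals
an area fraction exactly. The denominator is the species' whole range by
default; a `clip=(mask, country)` argument restricts both numerator and
denominator to one country for the in-country variant, and an empty range
after clipping is an explicit error, never a silent 0/0. Rankings within
an IUCN category break ties lexicographically by species id. Richness is
a plain sum of range masks, assuming presence across the entire range.

## Consumption arithmetic

`units_per_year × grams_per_unit / 1e6` tonnes, exact; shares of supply
are percentages rounded half-up to one decimal for presentation (the raw
value is always returned alongside). Shipped defaults describe the UK
biscuit case study — 12 × 10⁹ biscuits/year, 4.4 g sugar and 5 g
chocolate per biscuit, wheat entering as a given 96,000 t (its per-unit
mass is not published), against 7,276,708 t domestic sugar, 14,030,964 t
domestic wheat, and 162,108 t cocoa imports. These are inputs, not
results; the module recomputes everything from them.

## Synthetic data

Generators are pure functions of a `SynthConfig`; all randomness comes
from numpy's PCG64 seeded from `cfg.seed` through per-stream CRC32-derived
`SeedSequence` keys, so outputs are identical across runs and platforms
and independent across streams (one stream per crop, per stage).

* **Crop surfaces** — lognormal over Gaussian-smoothed white noise
  (default sigma 3 cells) with a spatially clustered zero set: a second
  smoothed field thresholded at its own empirical quantile, so the
  realised zero fraction tracks the 0.5 default closely (global crop
  rasters are mostly empty outside growing regions). Harvested area =
  production / smooth positive yield; physical area = harvested /
  multi-cropping factor ≥ 1, so physical ≤ harvested everywhere.
* **Intensity surfaces** — log-values re-standardised to the configured
  (mean, sd) exactly; WAT is shifted so the exceedance fraction above one
  equals `wat_exceed_prob` (default 0.3) up to grid granularity, putting
  mass on both sides of the sustainability threshold.
* **Country partitions** — multi-source breadth-first flood fill from
  random seed cells; every region is 4-connected by construction because
  each cell is reached from a neighbour in its own region.
* **Trade networks** — constructed origin-first so the truth is exact
  under proportional-mix tracing: exporters produce and ship but never
  import (their supply is origin-pure), parcels travel through dedicated
  pass-through hubs (zero production, all inflow forwarded to a single
  onward destination) with chain depth uniform up to `reexport_depth`,
  and terminal consumers never re-export. Any of those three properties
  failing would let the proportional mixing re-blend origins and the
  construction attribution would no longer be the fixed point; with them,
  recovery is exact and the recorded truth is meaningful. Production and
  consumption balance exactly.
* **Species ranges** — connected blobs grown by random frontier
  expansion, sizes uniform on [20, 400] cells at the 100×100 default,
  categories drawn from a configured distribution (uniform over
  CR/EN/VU/NT/LC by default); each species' true overlap fraction against
  the supplied crop layer is counted directly at generation time.

Default sizes (100×100 grid, 6 countries, 30 species, 8-country trade
network, depth-2 chains) run the full pipeline in seconds. What the
generators do **not** emulate: the marginal distributions of real crop
rasters (they are smoothed-noise surrogates, not calibrated to Monfreda/
MapSPAM), latitude-dependent cell areas, real country shapes and trade
topology, range shapes with elevational limits, or reporting noise in
trade data. Green tests therefore demonstrate the *algorithms* are
correct and the pipeline is deterministic; they do not validate the
published magnitudes, which depend on external rasters and trade data
this package deliberately does not download.

## Determinism and degenerate inputs

All tie-breaks are fixed (row-major cell order; canonical indicator
order; lexicographic ids; country-name ordering in tables). CSVs are
written with a fixed float format; rasters with Python float `repr`
(round-trip exact for float64). Rerunning any stage with the same config
and seed is byte-identical, which the test suite and the acceptance
script both verify. Degenerate inputs have documented behaviour rather
than undefined results: empty layers are errors for normalization,
classification and ranking; constant layers normalize to zero and class
as all-medium; an all-invalid production surface yields all-invalid
impact layers; a nodata sentinel colliding with a real value is a write
error.

## Known limitations

Cells belong wholly to one country; overlap fractions are unweighted cell
counts (an area-weighted variant would be needed on non-equal-area
grids); the origin-tracing model assumes perfect mixing within each
country's supply pool and no stock carry-over between periods; dry-matter
fractions and item mappings are configuration, not data; and the
published headline magnitudes (country impact totals, named-species
overlap percentages) are out of reach without the external global rasters
and are not asserted anywhere in the package.
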