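# Methods

This note documents the model implemented by `lifescore`, the assumptions
behind it, the defaults that matter, what the synthetic-data generator does
and does not emulate, and the numerical and design choices made where the
design was genuinely open.

## The metric

The score assigned to a coarse grid cell is the marginal change in the
expected number of species extinctions, per km² of land actually changed,
caused by transforming that cell alone. The chain is:

1. **Area of Habitat (AOH).** For each species-season, AOH is the area of
   fine pixels that lie inside the selected range components, whose
   elevation falls within the species' limits (inclusive at both ends), and
   whose land-cover class matches the species' preference set. Two AOHs are
   computed: *current* (against present land cover, extant/possibly-extinct
   range) and *original* (against potential natural vegetation, additionally
   including extinct-coded range — the species' habitat in the absence of
   people).
2. **Persistence.** The remaining fraction `x = A_now/A_orig` is mapped to
   a persistence probability by a capped monotone curve (below). Species at
   or above their original AOH persist with probability 1: the framework
   deliberately grants no credit for human-driven abundance above the
   original state.
3. **Marginal change.** Applying a scenario's pixelwise transform to one
   cell changes each species' AOH by the suitability difference inside that
   cell, evaluated within the species' *current* range — gains are allowed
   in currently unoccupied parts of the range, but not beyond the range
   (no colonization of new regions). The species' extinction-probability
   change is `P(x_before) − P(x_after)`; migratory species evaluate each
   season separately and combine them by the geometric mean of the two
   seasonal persistence probabilities, before and after.
4. **Summation and normalization.** Summing the per-species changes gives
   the change in the expected number of extinctions (linearity of
   expectation over independent Bernoulli extinction indicators; the
   package verifies this against direct Monte-Carlo simulation). Dividing
   by the area the scenario changes in the cell yields the per-km² score.
   Cells the scenario leaves untouched are nodata, encoded as NaN — zero is
   a legal score and is never used as nodata.

Marginality is a deliberate definition, not an approximation: each cell is
scored under a change to that cell alone, and interactions between cells
are quantified separately by the scalability simulations rather than
modelled at scoring time.

## Persistence curves

Two families are supported, both capped at 1 and evaluated in double
precision with the cap applied after the power/exponential:

* **Power law** `P(x) = min(1, x^z)`, default `z = 0.25` — the standard
  species–area-derived exponent in the persistence-score literature. The
  sensitivity analysis uses `z ∈ {0.1, 0.25, 0.5, 1.0}` by default; `z = 1`
  is the linear limit in which a unit of habitat loss has the same impact
  regardless of how depleted the species already is.
* **Modified Gompertz** `g(x) = exp(−a·e^{−bx}) / exp(−a·e^{−b})`, defaults
  `a = 5`, `b = 6`. The sigmoid is rescaled so `g(1) = 1` exactly (the
  normalizer is evaluated with the same vectorized exponential as the
  numerator so the equality holds in floating point). The shape expresses
  the disproportionate impact of demographic stochasticity at low remaining
  fractions. The exact parameterization of this family is a package choice;
  both parameters are exposed in configuration.

## Land-cover vocabulary and matching levels

The class vocabulary is a small closed set mirroring the two-level
structure of the IUCN habitat classification: natural level-2 classes
(moist/dry forest, shrubland, natural grassland, wetland, desert) collapse
to level-1 parents; arable, pasture and urban are artificial and mapped at
level 2 only. The PNV layer carries level-1 natural codes; the current
layer carries level-2 codes. Matching therefore differs by layer: original
AOH matches at level 1 throughout, while current AOH uses *mixed* matching —
natural preferences collapsed to level 1, artificial preferences exact at
level 2. This mirrors the finest matching a level-1 PNV product supports
and is the reason level-1 AOH is always at least level-2 AOH for the same
natural preference set.

Scenario transforms are role-driven through a crosswalk rather than
hard-coded class names: conversion sends every non-urban pixel to arable;
reversion sends arable and pasture pixels to their PNV class. Urban land is
never modified by either scenario — pasture plays a dual role (convertible
under conversion, restorable under reversion) by construction.

## Species filtering

Species are excluded, with machine-readable reason codes logged to CSV, when
they have missing preference or elevation data (`MISSING_DATA`; explicitly
unbounded elevation is valid data), inhabit caves or subterranean habitats
(`CAVE`), carry a marine/freshwater systems label (`SYSTEMS`), or have no
measurable AOH either currently or originally (`NO_AOH`, necessarily a
second pass after AOH computation). Range components contribute only with
presence extant/possibly-extinct (plus extinct for original AOH), origin
native/reintroduced/uncertain and seasonality resident/breeding/
non-breeding/unknown; passage and introduced components never contribute. A
species with a breeding range but no mapped non-breeding range is treated
as having a single, resident-like season and flagged in the log.

In the AOH-remaining summary, migratory species contribute the lower of
their two seasonal fractions. Species whose current AOH is zero have
fraction 0, which is log-undefined: they are excluded from geometric means
but counted and reported separately. Species with zero original AOH have no
defined fraction and are dropped from the distribution.

## Grid geometry

The Earth model is a sphere of radius 6378.137 km (the WGS84 equatorial
radius), which reproduces the conventional figures for a 1 arc-min cell:
1.86 km on a side and 3.4 km² at the equator. A fine pixel of angular side
`d` at latitude φ has area `s²·cos φ` with `s = 2πR·d/360`; areas depend on
row only. Grids are cell-edge aligned, row-major north to south, with
half-open cell intervals. The fine-to-coarse ratio is required to be an
integer (`fine_factor`), making aggregation an exact block sum; real-data
runs at other native resolutions are expected to resample land cover to an
integer subdivision first.

## The synthetic world

The generator emulates the *statistical* structure the metric consumes, not
real biogeography. From a seed it derives: a smooth elevation surface
(low-frequency sinusoidal bumps scaled to a configurable relief, default
1500 m); a PNV layer assigned from elevation bands; a current layer holding
level-2 subtypes of the PNV classes with agriculture painted over them by a
placement rule (`none`, `all_arable`, `random`, or `gradient` — conversion
probability rising west to east, giving a known habitat-loss gradient); and
a sprinkling of urban pixels (default 2%). Species receive elliptical
ranges with log-uniform areas (default 8–200 fine pixels, spanning an
endemism spectrum; an optional `endemism_gradient` shrinks ranges toward
the north on the axis orthogonal to the loss gradient), preference sets
drawn from the natural classes present in-range (default breadth 2, with
15% of species also tolerating arable), elevation limits bracketing their
range's terrain, and — for a default 20% — disjoint breeding/non-breeding
half-ranges. Defaults produce 30 species over a 24×24-pixel, 6×6-cell
world, the problem size used throughout the test suite; the generator also
book-keeps each species' constructed current and original AOH by direct
pixel counting, which the AOH engine must reproduce exactly.

Because ranges are generated directly as fine-grid masks, the geometry
library enters only through the optional GeoJSON polygon reader, keeping
rasterization variance out of the numerical tests. What passing tests on
this world do **not** show: realism of spatial pattern, climate effects,
taxonomic range-size differences, habitat condition or fragmentation — the
generator validates the *computation*, not the ecology.

## Scalability simulations

Two non-spatial Monte-Carlo designs quantify when per-cell map values
misestimate the impact of actions at other scales, using a region profile
of per-species occupancy probabilities (share of regional area holding the
species' habitat, i.e. a homogeneous-random-distribution assumption),
global AOH states and a representative cell area:

* **Large actions**: `k = round(size/cell_area)` cells scattered without
  replacement; each hits species *s* independently with probability `p_s`.
  The true impact evaluates the curve once at the total loss; the
  map-derived estimate sums single-cell marginal impacts evaluated at the
  unperturbed state. Ten geometrically spaced sizes × 100 replicates by
  default.
* **Sub-cell actions**: one cell, an action of side 0.05–1 arc-min; the
  species present are fixed once per action; the map-derived estimate is
  the cell's per-km² score times the action area.

The primary deviation statistic per replicate is
`|Σ approx − Σ true| / |Σ true|`, which is scale-free in species count; the
literal per-species sum of relative deviations is emitted alongside as a
secondary column because both readings of "summed relative deviation" are
defensible. For concave curves the map-derived estimate understates true
losses (marginal slopes are shallowest at the unperturbed state), so the
signed deviation is non-positive and its magnitude grows with action size;
the linear curve makes both estimates exact at every size, a property the
tests assert to 1e-9.

## Predictor layers and regression tables

Three coarse layers decompose score variation: **richness** (count of
species whose current *range* — not AOH — overlaps the cell), **endemism**
(mean over species with current AOH in the cell of the cell's share of
their global current AOH) and **habitat loss to date** (mean over the same
species of `clamp(1 − fraction_remaining, 0, 1)`, so beneficiaries of
human land use contribute zero). The differing presence definitions are
intentional and follow the three quantities' meanings. Regression tables
keep predominant-sign scores only (positive for conversion, |negative| for
reversion), log10-transform response and predictors, drop cells with any
non-finite transform, sample `n_cells` without replacement per run, and
standardize each run's columns to zero mean and unit variance —
log-transform before standardization, recorded here because the opposite
order is also conceivable. Model fitting (e.g. a GAM with a spatial
smoother) is deliberately left to external statistical tooling.

## Numerical choices

* Per-species contributions to a cell's numerator are accumulated as a
  stack and reduced with numpy's pairwise summation; at the package's
  species counts this keeps accumulated rounding far below the 1e-12
  relative tolerance the oracle-equivalence tests enforce, without explicit
  compensated summation.
* `A_scen = A_now + ΔAOH` is clipped at zero before the curve is evaluated;
  the quantity is non-negative mathematically and the clip only absorbs
  last-ulp artifacts.
* Ties and degenerate inputs: empty range selections yield empty masks (and
  eventually `NO_AOH`), not errors; species with zero original AOH in any
  season are skipped by the scorer with a log entry; cells with zero
  changed area are NaN; an empty species list yields a zero map with the
  same nodata structure.
* All randomness flows from a single root seed split per stage with
  `numpy.random.SeedSequence`; every CLI stage writes a manifest with the
  config hash and output checksums, and rerunning any stage with the same
  seed and config is byte-identical.

## Problem sizes

The default test and reproduction configurations use a 6×6-coarse-cell
world with 30 species (scoring, oracle equivalence, sensitivity), a
12×12-cell world with 100 species (predictor rank correlations, where more
cells stabilize the statistic), 10⁶ Monte-Carlo replicates for the
expected-extinctions identity, and 100–200 replicates per action size in
the scalability simulations. These sizes were chosen so each analysis's
statistic is stable across seeds while the whole suite remains quick to
run.

## Known limitations

Habitat quality, patch size, fragmentation, connectivity, time lags
(extinction debt, restoration delay) and threats other than land-cover
change are outside the model, as are projected coordinate systems and
ellipsoidal geodesy. Scores for restoration should not be read as
symmetric-in-practice with conversion: the model's directional symmetry is
a property of the persistence algebra, not of real-world habitat recovery.
The synthetic world validates computation rather than ecology, and the
global headline statistics of real-data analyses are functions of the real
datasets, which this package does not ship.
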