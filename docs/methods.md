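# Methods

This note records the models, numerical choices and known limitations
behind `geocontext`, in the order the pipeline runs.

## Projections and buffers

All areal arithmetic happens on a planar frame in meters. The default
frame is a per-buffer **azimuthal equidistant projection on a sphere whose
radius is the WGS84 Gaussian radius of curvature** `sqrt(M·N)` at the
reference latitude, centered on the buffer's own location. Centering on the
point makes the projection distance-true from the center, so every buffer
vertex sits at exact ground distance; using the local Gaussian radius keeps
the residual ellipsoidal error quadratic in (distance/earth radius) — a few
parts per million over the ≤5 km neighborhoods this package targets, and
still ~1 m over 50 km when projecting tract polygons into a buffer's frame.
The forward/inverse pairs are closed-form and exact inverses, so WGS84
round trips are accurate to ~1e−12 degrees (contract: 1e−6).

A spherical transverse Mercator on the same Gaussian sphere
(`tmerc:<lat>,<lon>`) is provided as an explicit alternative frame, e.g. to
emulate a state-plane-style zone projection centered away from the buffer;
the projection-insensitivity tests show buffer areas under the two families
agree within 0.5 % at ≤5 km radii. Projection identifiers are limited to
these two families; there is no zone lookup table, so reproducing a
specific published state-plane zone requires passing its center
explicitly. All computation is 2-D; elevation is ignored.

Buffers are regular polygons **inscribed** in the ideal circle, 64 segments
by default (minimum 16). The inscribed n-gon area is
`πr²·(n/2π)·sin(2π/n)` — 99.84 % of the disk at n=64 — and the boundary
sags below the circle by the sagitta `r·(1−cos(π/n))` (≈1.2 m at r=1000 m,
n=64). Area converges monotonically in n; tests pin this at n ∈ {16, 64,
256}.

## Areal interpolation

Source units (census-tract-style polygons) are assumed to carry uniformly
distributed measures. The buffer is partitioned so each piece lies in
exactly one unit; pieces with zero intersection area are dropped. For a
piece with intersection area `aᵢ` in a unit of area `Aᵢ` and value `vᵢ`:

- **count** measures: estimate `Σ (aᵢ/Aᵢ)·vᵢ` — conserves totals exactly
  when the buffer equals a union of units (pycnophylactic property);
- **proportion** measures: estimate `Σ aᵢ·vᵢ / Σ aᵢ` — intersection-area
  weighting, the standard reading of area-weighted averaging; output is
  bounded by the min/max of the intersecting units' values.

Unit areas `Aᵢ` are computed from the unit polygon in the buffer's planar
frame, not from attributes, for internal consistency; land-area semantics
enter as their own count measure (see density below). Invalid polygons are
repaired by zero-width buffering; irreparable units are skipped with a
warning.

**Missing values** (the data sources are silent on policy): missing-valued
units are excluded from the sum/average, and each output row reports
`coverage_fraction` (covered area / buffer area) and `n_missing` so biased
rows are visible and filterable; `strict=True` returns a missing result if
any intersecting unit is missing. Buffers extending beyond the dataset are
computed from covered pieces only, with `coverage_fraction < 1` flagging
the gap — never silently.

**Population density** is interpolated population divided by interpolated
land area (a count measure in m², excluding water), giving persons per m²
of land rather than per m² of disk; non-positive land area yields a missing
result with a warning.

Multi-year datasets key measures as `name@year`; there is no temporal
blending.

## Geocoding

The gazetteer is a local table of normalized address records (house
number, street name, street type, city, state, ZIP, coordinates).
Normalization lowercases, strips punctuation, expands postal abbreviations
(`ave`→`avenue`, 16 entries), keeps directionals (`ne`, `sw`) verbatim, and
drops trailing country designations. The match score is a weighted
component agreement: house number 0.30 (exact), street name 0.40
(Jaro–Winkler), street type 0.10, city 0.10, state 0.05, ZIP 0.05 (exact);
a component absent on both sides counts as agreement, absent on one side as
disagreement. `rating = round(100·(1−score))`, floored at a 0.5 score below
which no match is returned; ties break lexicographically by normalized
record address. Rating 0 is reserved strictly for exact normalized-token
equality (a rounding guard enforces the iff). This formula is an auditable
stand-in for street-database geocoder ratings, not a claim of equivalence
to any of them; intermediate values are comparable within this package
only. Scope is US-style addresses.

The verification output is a worst-first CSV (unmatched rows first, then
descending rating) with a `flagged` column (`rating > threshold`, default
10); the interactive-map review step of GUI geocoders is deliberately
replaced by this file export so no address ever leaves the process.

## Point aggregation

Membership is tested against the polygonal buffer (not the ideal circle)
so areal and point operations share one geometry, with a closed boundary:
on-boundary points count, implemented with a 1 µm grace distance that
absorbs projection round-trip float error. Points in the annulus between
the polygon and the circle (within the sagitta of the boundary) may be
excluded relative to an ideal-disk count; the distance-oracle test excludes
that ambiguous annulus explicitly. No kernel or distance-decay weighting.

## NE-WAS screen

Per measure: complete cases (≥10 required, else skipped with reason),
z-score standardization, univariable logistic regression by maximum
likelihood (statsmodels), two-sided Wald p, strength `−log10 p`. The
coefficient is a log-odds change per SD, so results are invariant to affine
rescaling of measures. Bonferroni significance is `p < α/m` with `m` the
measures actually tested (skipped measures do not count). Complete or
quasi-complete separation (detected via statsmodels' separation signals or
a degenerate Wald fit: |coef| > 40 or SE > 1000) is flagged and reported at
a capped strength of 300 rather than a spurious huge value. Constant
measures are skipped; a constant outcome is a global error. The screen is
univariable by design — no covariate adjustment, no spatial correlation
modeling.

## Synthetic data

The generators define the study conditions for all tests:

- **Tract grids**: n×n squares (default 1 km cells) with constant or
  uniform-random count/proportion measures; `land_area` always included.
- **Cities**: annular-sector tracts (8 rings × 12 sectors × 750 m by
  default, reaching 6 km) so ring densities are exact: each tract's
  population is the closed-form integral of the density profile
  `d(r) = d₀·e^(−r/λ)` (compact; defaults d₀ = 0.006 persons/m² ≈ a dense
  US urban core, λ = 2000 m) or `d(r) = d₀` (sprawl) over its land area.
  Water-masked sectors halve land area and population together, leaving
  density per land area unchanged. `analytic_buffer_density` gives the
  closed-form buffer-averaged density used as the curve-fit model and
  oracle.
- **Points**: uniform-in-disk (r = R√u) or per-tract Poisson with rate
  proportional to a count measure.
- **Gazetteers**: numbered avenues on a 200 m grid with a truth table, so
  every clean generated address must geocode to its true coordinates with
  rating 0 (closure property), and abbreviation expansion is exercised.

What the synthetic data does *not* emulate: real tract shapes and
autocorrelated measure surfaces, address typo distributions, vintage/
boundary mismatches between datasets, and spatially structured outcomes.
Passing tests therefore demonstrate correctness of the geometry,
interpolation arithmetic, rating contract and screening statistics — not
robustness to real-data messiness.

## Verification choices and sizes

- Partition areas are checked against a rejection-sampling Monte-Carlo
  oracle: uniform points in the buffer polygon, piece area vs binomial
  expectation under the implementation's value as the null, |z| < 3 in the
  normal regime; sliver pieces with expected hit counts below 9 use a
  Poisson-style slack `3√μ + 3` instead, where the normal approximation is
  invalid. Test size: 20 random configurations × 10⁶ samples; the
  acceptance script reports the same statistic at 6 × 2·10⁵.
- Areal interpolation inherits a bias from the within-unit uniformity
  assumption when the true field varies inside units: on the compact city
  (750 m rings, λ = 2000 m) assembled densities sit ~5 % below the analytic
  curve at r = 1000 m, and the curve-fit recovers (d₀, λ) within ~5 %
  (tolerance 10 %). Ring-aligned radii would be exact; the misaligned
  default is kept deliberately as the realistic case.
- NE-WAS operating characteristics: family-wise error estimated over 500
  null replicates (m = 100 measures, n = 200) against α = 0.05 plus 3
  binomial standard errors; power for a standardized log-odds slope of 2.0
  at n = 500 over 200 replicates (≥95 % required). The acceptance script
  reports 300/150 replicates.
- The no-network contract is asserted by monkeypatching every socket
  primitive to fail and running the whole simulate→geocode→assemble→
  points→newas pipeline in-process.

## Known limitations

Administrative-unit (whole-tract) queries, population-weighted or
dasymetric interpolation refinements, road-network buffers, shapefile
input, kernel-weighted point aggregation and covariate-adjusted screening
are out of scope. The geocoder's intermediate ratings are package-specific;
only the endpoints (0 = exact, no-match) are portable contracts.
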