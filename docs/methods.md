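# Methods

This note documents the statistical procedures `lurkit` implements, the
numerical conventions chosen where the field leaves them open, what the
synthetic generators do and do not emulate, and known limitations.

## The model

For a pollutant measured at sites *i* = 1…n, the land-use-regression model is
ordinary least squares

  y_i = β₀ + Σ_j β_j x_ij + ε_i

where y_i is the temporally adjusted biannual mean concentration and x_ij are
GIS-derived predictors. The scientific content is not the OLS fit but the
*supervised* construction of the predictor set: every candidate carries an
a-priori direction of effect (traffic, built-up area, population, industry →
positive; natural land, urban green, altitude → negative; water and area
indicators unconstrained), and a candidate enters only when its fitted sign
agrees with that prior. This is what keeps small-sample models physically
interpretable and transferable.

## Predictor engineering

Buffers are planar Euclidean circles in a projected metric CRS; at study-area
scale (≤ tens of km) geodesic corrections are negligible, and reprojection is
deliberately out of scope — inputs must arrive projected. Circles are
polygonised with 64 segments per quadrant (area error ~1e-4 relative, an
order of magnitude inside the 0.5 % tolerance the engine is validated to).
Conventions that needed a decision:

* **Area sums** are per-polygon intersection areas, summed. Layers are assumed
  not to self-overlap within a class (true of building footprints and
  exclusive land-cover mosaics); overlapping inputs would double-count.
* **Nearest-road distance** is clamped below at a configurable minimum
  (default 1 m) before inversion, keeping inverse-distance metrics finite for
  a site on a centreline. Monitoring sites sit at residential façades, never
  exactly on a centreline, so the clamp is a numerical guard, not a model
  feature. Equidistant ties resolve to the higher-intensity segment, then the
  lexicographically smaller segment id — deterministic, and conservative given
  traffic's positive direction of effect.
* **Raster lookup** is nearest-cell ("direct overlay", no interpolation);
  boundary points belong to the half-open cell [x₀+i·c, x₀+(i+1)·c) ×
  [y₀+j·c, y₀+(j+1)·c). Population counts in a buffer sum the cells whose
  centres fall inside the circle.
* **Altitude transforms** use the natural log; non-positive altitudes are
  rejected as invalid input for log/√ rather than silently clamped.
* **Major road** means modelled intensity ≥ 5000 veh/day; heavy-traffic loads
  weight intensity by the heavy-vehicle share.

The standard inventory enumerates 174 variables (12 building-area radii, 9
population radii, 8 land-use classes × 9 radii, 7 water radii, 5 road
statistics × 12 radii, 8 nearest-road metrics, 3 altitude forms, 3 dispersion
overlays), plus 0/1 area indicators against a declared reference area.

## Temporal adjustment

The correction factor for period *p* is (biannual reference mean)/(reference
mean in *p*); each valid measurement is multiplied by its factor and the
arithmetic mean is taken (no transform — the averaging is untransformed by
design). The identifying assumption is that the fixed reference monitor's
temporal pattern is shared by the whole area; under that assumption the
procedure is exactly unbiased, and scale-equivariant by construction.
"Season" is operationalised as "measurement period", and the exclusion rule
is `min_seasons = 2`. Whether the biannual reference mean is computed from
all days or campaign periods only is the caller's choice — the reference
series carries the value as given.

## Screening

Rule 1 (mode count) fails a candidate when fewer than five sites differ from
its most common value; modal ties resolve to the smallest value. Rule 2/3
(outlier fences) fail it when max > P90 + 3·(P90−P10) or min < P10 − 3·(P90−P10)
— a deliberately looser variant of the usual quartile fences. Percentiles use
linear interpolation between order statistics (the default of the major
statistics environments; the method is not otherwise prescribed). When
P10 = P90 the fences collapse and any deviating value fails; such columns are
in practice also caught by rule 1. Area indicators and forced dispersion
terms bypass screening — they are introduced deliberately regardless of their
distribution. Screening is re-run for every fit because eligibility depends
on the site subset.

## Selection and finalisation

Admission step: among screened candidates, fit each added to the current
model; qualifiers must have the declared sign, p < 0.10 (two-sided t-test —
the direction constraint is enforced on the sign, not via one-sided tests),
adjusted-R² gain ≥ 0.01 (applied from the second admission; the first needs
only sign and p), and must not flip the sign of any earlier directional term.
The largest gain wins; exact ties resolve lexicographically by name so reruns
are identical. Finalisation then (a) iteratively removes the worst p ≥ 0.10
term — worst-first, because simultaneous removal can strand significant
terms; (b) while any VIF ≥ 3 or any Cook's distance ≥ 1, removes the most
recently admitted non-forced offending term and refits, logging each action.
The remedy for VIF/Cook violations is not prescribed anywhere; removing the
latest admission is conservative and reproducible. Forced terms (dispersion
surfaces, area indicators) are never removed but count toward diagnostics.
Removal never re-opens admission. RMSE uses the n denominator (population
form), configurable to n−p−1; published tables do not disclose the
convention. Candidates are filtered by the p < 0.10 gate before the gain is
maximised; the alternative order differs only in pathological ties.

Trained models record per-predictor training ranges and the set of
truncation-exempt (dispersion-derived) predictors, so transfer behaves
correctly later.

## Validation

LOOCV refits coefficients per fold with the variable set fixed; R² is the
squared Pearson correlation of observed versus held-out predictions (the
conventional LUR definition), with 1 − PRESS/SST reported alongside because
the two diverge under bias. The explicit refits are verified against the
closed-form identity e_i/(1−h_i). LOAOCV refits on the complement of each
area; a variable constant in training but different in the held-out area
necessarily encodes that area (an area indicator), making prediction
impossible — the operation refuses, mirroring the restriction of
area-indicator models to their own areas. A variable constant at the same
value everywhere in training is merely uninformative and is dropped from the
fold with a flag.

Moran's I uses all-pairs weights w_ij = 1/d_ij² (no cutoff); duplicate
coordinates are an error. Significance defaults to a seeded two-sided
permutation test (999 permutations) around the null expectation −1/(n−1),
with a normal-approximation option. Residual dependence on study area is a
one-way ANOVA F-test; single-site areas are flagged and excluded.

## Transfer

"Within X km of the sites" is implemented as minimum point-to-training-site
distance ≤ X km — equivalent to polygonised buffers for assignment and
simpler to test. When several local models are in range the nearest training
site wins, ties by area name. Outside all radii, the alpine model applies at
altitude ≥ 1000 m and the non-alpine model below; a point there without an
altitude is an error. Non-exempt predictors are clamped to their training
min/max; dispersion predictors pass through, since they represent regional
background and may legitimately exceed the training range.

## Synthetic data

The generators emulate the study design the pipeline targets: several
well-separated study areas (default 4, spaced 20 km so no 5 km buffer crosses
areas) with distinct background levels and altitude bases; ~40 sites per
area with half placed 5–30 m from a major road (street sites are deliberately
over-represented in such campaigns); lognormal road intensities (median
1500 veh/day, log-SD 1.2); three seasonal periods with shared factors
(1.3, 1.0, 0.7 — mean 1) and ~5 % multiplicative measurement noise; smooth
raster fields built from Gaussian-filtered white noise (a cheap stationary
random field standing in for a Gaussian-process draw). A separate direct
path samples predictor matrices with a prescribed correlation structure
(or monotone nested-buffer groups) for many-replicate statistical tests.

What the generators do **not** emulate: real topography, realistic road-network
topology (segments are independent straight lines), land-cover mosaics with
exclusive polygons, spatially autocorrelated measurement error, and
instrument-specific behaviour. Passing tests therefore demonstrate the
correctness of the algorithms under the stated statistical assumptions, not
the field performance of any particular model.

The parameter-recovery test uses n = 40 sites and 30 candidates — 3 true
iid predictors with positive directions and 27 noise candidates in 9
correlated triplets (within-triplet ρ = 0.8, emulating nested buffer
families) with randomly assigned ± directions — and noise SD chosen so the
population R² is 0.70. Its thresholds were pinned from a pre-build run of
the independent enumeration oracle: recovery 0.98, mean false admissions
≈ 1.1 before the VIF/Cook gates, coefficient RMSE mean 0.194 / max 0.402
(test bounds 0.25 / 0.45 with Monte-Carlo margin). The false-admission rate
is sensitive to the inventory's correlation and direction structure:
direction-free, uncorrelated noise candidates roughly triple it.

## Problem sizes

Test and pipeline problem sizes are chosen to exercise every code path at
the scale the statistics need (40 sites per fit, 50-seed recovery runs,
100-fixture oracle batteries, 2–3 area landscapes for end-to-end runs);
larger landscapes change runtime, not behaviour.

## Known limitations

* No regularised or spatial-error alternatives to OLS; no kriging or
  variogram modelling of residuals.
* Vector input is GeoJSON and raster input ESRI ASCII grid; no CRS handling.
* The shipped published model equations carry printed-precision coefficients
  and no training ranges (those were never published), so transfer with them
  truncates only if the caller supplies ranges.
* The multiplicative campaign model requires positive site means; truth
  configurations with large negative offsets relative to the intercept are
  clipped at a small positive floor.
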