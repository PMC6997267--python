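# Methods

## Problem and model

`geofoot` analyses the small-area geography of diabetic foot disease: for
each census data zone it computes crude outcome rates among people with
diabetes, asks where zones of high (or low) rates cluster spatially, and
tests whether those clusters concentrate in the most deprived quintiles of
a multiple-deprivation index.

### Outcomes and windows

Per-person outcomes are a diabetic foot ulcer (DFU; any previous or active
ulcer — history counts, following risk-stratification practice), a lower
extremity amputation (LEA; major and minor pooled), and death preceded by
a DFU and/or an LEA (the qualifying event dated on or before the death
date; a same-date tie counts as "preceded", since registry date resolution
is coarse). Aggregation runs over a *full* registry window (2002-01-01 to
2016-11-07) for LEA and mortality, and a *subset* window (2012-01-01 to
2016-11-07) for DFU prevalence, reflecting the later completion of
systematic foot screening. The window denominator is every person
registered by the window end; requiring survival into the window was
considered and deliberately not adopted (registration is the recorded
fact; survival status at an arbitrary cut date is not).

### Rates

Prevalence is reported in percent, `100 * cases / population`; mortality
incidence per 10,000 person-years uses the closed-cohort approximation
`10000 * events / (population * years)` with the full window counted as 14
years. No age/sex standardisation is applied: crude rates are the mapped
quantity, and adjustment is left to explanatory modelling outside this
package's scope. Zones with zero denominator produce missing values (never
a silent 0); zones with denominators below 5 are flagged low-confidence
but still computed. Reported values are rounded half-away-from-zero to one
decimal place; all computation uses full precision.

### Spatial weights

The neighbourhood model is a **fixed distance band on zone centroids,
corrected by queen contiguity**: `w_ij = 1` if the centroid distance is at
most the band threshold *or* the polygons share an edge or corner, else 0.
The union rule is the natural reading of "band, then corrected for shared
boundaries": contiguous pairs the band misses are added, and both schemes
are also available standalone for sensitivity analysis. Weights are binary
and symmetric — the standard fixed-distance-band Gi* convention — not
row-standardised. The default band threshold is `"auto"`: the smallest
distance at which every zone has at least one neighbour (the maximum
nearest-neighbour distance), logged on the matrix for reproducibility
because no single threshold suits both dense urban cores and sparse
peripheries. All coordinates are assumed planar; geographic (lon/lat)
input is refused with an instructive error rather than silently treated
as Euclidean.

### Getis–Ord Gi*

For zone i, with self-inclusion `w_ii = 1`,

    z_i = (Σ_j w_ij x_j − X̄ W_i) / (S √[(n Σ_j w_ij² − W_i²)/(n−1)])

where `W_i = Σ_j w_ij`, `X̄` and `S` are the global mean and population SD
of the zone values. z_i is treated as a standard-normal deviate; zones are
binned two-tailed at |z| ≥ 1.645 / 1.960 / 2.576 (90 / 95 / 99%
confidence), sign giving hot versus cold, ties at a threshold taking the
higher-confidence bin. Degenerate cases are made total by convention: a
constant value field returns z = 0 everywhere (with a warning), and a zone
whose neighbourhood spans the entire map has numerator and variance both
zero and also returns 0. Zones with missing rates are excluded (rows and
columns dropped from the weights) and reported on the results object
rather than zero-filled — imputing 0 would manufacture cold spots. No
multiple-testing correction is applied by default, matching the raw
two-tailed thresholds of standard hot-spot practice; p-values come from
the normal approximation only.

### Deprivation association

Hot-spot (and cold-spot) zones, significance tiers pooled, are counted per
deprivation quintile and tested with a one-sample χ² goodness-of-fit test
(df = 4). The default expected proportions are each quintile's share of
data zones — spots are zone-level events, and quintiles need not contain
equal numbers of zones within one health board; uniform 1/5 is available
as an option and both choices are recorded in the report. The test refuses
(raises) on zero totals or zero expected cells instead of returning NaN.

## Synthetic data generator

The linked health-register data the analysis was designed for are not
publicly available, so the package ships a generator that emulates their
statistical structure; its defaults are the study conditions.

* **Geography** — a Voronoi tessellation of the unit square, seeds
  contracted towards the centre (coordinate-wise power transform, exponent
  1.6), so central zones are small and peripheral zones large, emulating
  the urban/rural size gradient of census data zones. Cells are bounded by
  mirroring seeds across the square's edges, so the polygons exactly
  partition the square and the queen-contiguity graph is valid. Default
  200 zones (the study geography has 1,460; 200 keeps replicated
  experiments cheap while preserving the structure).
* **Populations** — lognormal with mean 760 (the census design target) and
  coefficient of variation 0.3: the source only publishes the mean, and
  CV ≈ 0.3 gives realistic dispersion for population-normed small areas
  without degenerate tiny zones.
* **Deprivation** — Gaussian noise on zone centroids smoothed with a
  Gaussian kernel (range = `deprivation_smoothness`, default 0.15 of the
  map width), then rank-cut into five equal-count quintiles, quintile 1 =
  highest score = most deprived. Kernel-smoothed noise is a deliberately
  cheap stand-in for a Gaussian random field: it produces tunable spatial
  autocorrelation (verified against a permutation null) without a GP fit.
  0.15 makes quintiles form contiguous neighbourhoods, as real
  multiple-deprivation surfaces do.
* **Risk surface** — per-zone outcome probability = base rate × quintile
  relative risk × planted-cluster multipliers, capped at 0.99. Defaults:
  base DFU 0.046 and LEA 0.013 (the overall study rates), death-given-
  event 0.30 (reproducing the order of ~1,600 deaths among ~5,000
  event-positive people in a 112k cohort); quintile relative risks
  (2.5, 1.5, 1.0, 0.8, 0.6), matching the four-to-five-fold most-to-least
  deprived spread. Planted clusters cover the centre zone plus all zones
  within a queen-contiguity hop radius.
* **Cohort** — one person per head of zone population; Bernoulli event
  draws; 80% of amputations are forced to carry an earlier-or-same-date
  ulcer (the only published dependence structure); death is only drawn for
  people with an ulcer or amputation history and dated after their last
  event; all event dates uniform over the registry window. The cohort is
  closed — no migration between zones — mirroring the source registry's
  own stated simplification.

What the generator does **not** emulate: age/sex structure, diabetes type,
ethnicity, within-quintile risk heterogeneity (exposed as config knobs
only through the relative-risk vector), real coastline/estuary geography,
and person-time censoring. Tests passing on synthetic data therefore
validate the statistical machinery — weights, Gi*, classification,
association — and the direction of the deprivation gradient, not the
study's real-data effect sizes or spot counts, which require the
confidential linkage.

## Numerical and design choices

* All randomness flows from one master seed through named
  `numpy.random.Generator` streams per stage, so geography, quintiles and
  cohort are bit-reproducible and independently re-drawable.
* The sparse Gi* implementation is checked against a naive dense-loop
  evaluation of the formula to 1e-12 on random instances.
* Quintile ranking uses a stable argsort; rank ties (measure-zero under
  continuous scores) resolve by zone order.
* The distance band is inclusive (≤ threshold) with a 1-ulp tolerance so
  the critical pair defining the "auto" threshold is always included.
* Queen contiguity uses an STRtree `dwithin` query with snap tolerance
  1e-9 of the map width, absorbing sliver gaps in real polygon layers.
* GeoJSON ring orientation is normalised to RFC 7946 (exterior CCW) on
  both read and write rather than treated as an error, since real layers
  vary; coordinates round-trip exactly.
* SVG maps are byte-deterministic (fixed hash salt, no timestamp
  metadata) so rendered outputs can be diffed in tests and pipelines.

## Experiment sizes

Replicated experiments (planted-cluster recovery, null calibration) use
200-zone geographies with ~152,000 simulated persons per replicate and 100
replicates per arm — large enough that the planted ×3 cluster is
essentially always recovered (its centre z-score is ≈ 10 or more) and the
null hot-flag rate estimate has Monte-Carlo error well under a percentage
point, while a full run of the acceptance script completes in about a
minute.

## Known limitations

* The normal approximation for Gi* is taken as given (it is the method
  under study); the empirical null rate of ~5% per tail at the 90%
  two-tailed tier confirms it is adequate at these population sizes, but
  a conditional permutation test would be preferable for very small
  denominators.
* Raw-count χ² statistics against person-level quintile shares are not
  produced: the expected model used for them in the source report is not
  stated, so only zone-level spot associations are tested.
* Incidence uses population × window-years person-time; individuals'
  exact person-years (entry to death) are recorded in the cohort but not
  used by default.
* Shapefile input is not supported; convert to GeoJSON in a projected CRS.
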