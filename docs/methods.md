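# Methods

This note documents the models, conventions and design choices behind
`hiersdm`, in the order the pipeline applies them.

## Grid and raster conventions

All maps live on a regular geographic lon/lat lattice (`GridSpec`), default
cell size 0.25° (≈30 km at mid latitudes). Cells are half-open and
lower-inclusive: a point on a cell's southern or western edge belongs to
that cell, so every in-extent point maps to exactly one cell. Row 0 is the
southernmost row. Aggregation from finer lattices is an unweighted block
mean (no latitude/area weighting): downstream logic — TSS thresholds, zone
classification — is invariant to monotone aggregation choices at the scales
the package targets, and the unweighted mean keeps the operation exactly
invertible in tests. A coarse cell is nodata only when *all* its fine
contributors are nodata ("any valid contributor wins"), which avoids eroding
coastlines at coarse resolution.

On-disk format is a human-readable ASCII grid (header
`n_rows n_cols min_lon min_lat cell_size nodata`, then one line per row,
south first, `%.17g` values so round-trips are exact to 1e-9 and better).
Projected or rotated grids are out of scope.

## Synthetic data: what it emulates, what it does not

`synthetic` generates the study world. Predictors are Gaussian random
fields smoothed to a configurable correlation range (default 3 cells),
standardized to mean 0 / sd 1, and tagged `climate_*` or `habitat_*`;
optional near-duplicate layers (r > 0.99) plant the collinearity that
stepwise VIF must find. A species' truth is
`logistic(β₀ + Σ βᵢxᵢ + Σ γᵢxᵢ²)`; when a prevalence target is set, the
intercept is re-solved by bisection so mean suitability matches the target
within 0.005. Records are drawn cell-proportionally to `truth × bias`
(with replacement, so per-cell thinning has real work), placed uniformly
within the cell, and annotated with a log-normal coordinate uncertainty
(log-mean `log 5000` m, log-sd 1 — deliberately straddling the 15 km
precision filter) that is missing with probability 0.2. Five per cent of
records are corrupted into one of the three cleanable error classes (zero
coordinates, lon copied to lat, exact duplicate) and labelled in a
`raw_flags` column that only tests read.

The generator emulates: spatial autocorrelation, predictor collinearity,
suitability-driven occupancy, effort bias, precision metadata gaps, and
classic coordinate errors. It does **not** emulate: dispersal limitation or
spread dynamics, temporal trends, taxonomic misidentification, country
centroid/institution artefacts (handled as configurable exclusion lists
instead), or non-stationary niches. Passing tests therefore demonstrate the
machinery is correct and the statistical design recoverable under those
listed difficulties — not that real GBIF data meet these assumptions.

## Occurrence preparation

Three ordered stages, each counted in a provenance ledger: (1) keep
georeferenced human/machine observations with coordinate uncertainty
≤ 15 000 m — the cap is inclusive, and a missing uncertainty is dropped
under the *certain* variant but kept under *certain+NA*; (2) remove (0,0)
points, exact lon==lat records, exact duplicates (first survives) and
records within a configured radius of exclusion points (equirectangular
distance, adequate below ~100 km); (3) thin to one presence per grid cell.
The pipeline is idempotent, and *certain* presence cells are always a
subset of *certain+NA* cells for the same input. The global tier uses
*certain+NA* (coverage matters most when estimating the climatic niche);
the regional tier uses *certain* (precision matters most at 0.25°).

## Predictor screening

VIF of a variable is `1/(1−R²)` from an OLS regression (with intercept) of
that variable on the others, over all valid cells of the modelling extent —
not only presence/pseudo-absence points — because screening happens once
per tier before any species is fit. Stepwise removal drops the largest-VIF
variable (ties: earliest column) until all survivors are ≤ 4. VIF is
scale-invariant, so screening uses raw values even though learners
standardize. Exact collinearity (R² ≥ 1−1e-12) maps to `inf`.

## Ensemble core

**Pseudo-absences.** Uniform draws without replacement from valid
non-presence cells; weights start at 1. At the regional tier, weights come
from the inverse-logistic transform of the projected global suitability:
`w = 1/(1+(p/(p−1))²)`, `w(1) := 0`. The transform is continuous on [0,1),
strictly decreasing, and satisfies `w(p) + w(1−p) = 1`. Global-tier
pseudo-absences stay unweighted. Defaults are 20 000 (global) and 5 000
(regional) per set at full scale; desk-scale runs shrink these through
`EnsembleSettings`.

**Members.** Each (algorithm, pseudo-absence set, CV run) triple is fit on a
class-stratified 70/30 split; pseudo-absence weights enter as multiplicative
case weights in the learner's loss (presences always weight 1). The roster:

| algorithm | implementation | notes |
|---|---|---|
| `glm_logistic` | unpenalized logistic on degree-2 polynomial features | the classical quadratic-response GLM |
| `gam_spline` | ridge logistic on per-predictor cubic splines (5 knots) | smooth additive responses |
| `fda` | two-class optimal scoring = weighted ridge regression of the class indicator on a spline basis, clipped to [0,1] | with two classes FDA reduces exactly to this regression |
| `gbm` | gradient-boosted trees, depth 3, shrinkage 0.01, 1000 trees (configurable) | |
| `maxent_like` | L1-regularized logistic on the quadratic expansion | optional, off by default |

A member's cutoff is the TSS-maximizing value on a 0.01 lattice over its
held-out 30 % (ties take the smallest cutoff). Members with evaluation TSS
≥ 0.7 are selected; if none qualifies, the `ceil(0.10·N)` best members are
kept so the ensemble is never empty.

**Committee average.** Each selected member's continuous map is binarized
at its own cutoff; ensemble suitability is the per-cell vote fraction
(values in {k/N}); the CV layer is the per-cell population sd / mean of the
votes, set to 0 where the mean is 0, then rescaled to [0,1] by the map's
maximum finite value (the "standardized between 0 and 1" convention).

**Ensemble binarization.** The ensemble cutoff is TSS-optimized against the
full presence / first-pseudo-absence-set data (not held-out data; a
flag-level alternative was considered but the full-data convention is the
default since the member-level selection already used held-out splits).
Range filling is `|predicted ∩ observed| / |predicted|`, undefined (`None`)
for an empty predicted range.

**Seeds.** One master seed per run; every stochastic stage derives a 31-bit
child seed by SHA-256 hashing the master seed with stage labels (species,
tier, pseudo-absence set, CV run). Full runs are bit-reproducible.

## Hierarchy

The region grid must be an aligned sub-extent of the world grid, so global
suitability is projected by exact clipping — no resampling. A species with
fewer presence cells than the configured minimum (default 30 global / 20
regional in the demo; the method's floor is ~30-50 cells) is skipped with a
logged reason and the multi-species run continues. If the global projection
is 1 everywhere on the region, all regional pseudo-absence weights are 0;
the run proceeds with a warning rather than failing.

## Zoning

Richness is the per-cell sum of species binaries (nodata only where every
species is nodata). The classification tree tests, in order: mean regional
CV (certainty), regional richness, and — on the uncertain branch — global
richness. "High" means **strictly greater** than the threshold, so cells at
exactly the printed central values (CV 0.5, richness `⌊n_species/2⌋`, i.e.
7 of 15) land in "low"; the source convention is unstated and the strict
rule makes the central values themselves classify deterministically. Zone
fractions partition valid cells; absent zones report zero cells and
undefined statistics rather than erroring (an empty zone is a legitimate
scientific outcome).

## Uncertainty surfaces

**MESS** uses the strictly-below percentile convention: with `p` the
percentage of reference values below the target, similarity is `2p` for
`p ≤ 50`, `2(100−p)` for `50 < p < 100`, and the linear extrapolation
branches `(t−min)/(max−min)·100` / `(max−t)/(max−min)·100` at `p = 0` /
`p = 100`. This makes a target at the reference minimum score exactly 0 and
anything outside the reference range negative. The per-cell MESS is the
minimum over variables; the reference set is the species' presence-cell
predictor values (training conditions). The stacked summary is the per-cell
fraction of species with MESS < 0.

**Half-ignorance** is `h/(n+h)` with half-saturation `h = 1` record per
cell by default: 1 with no records, 0.5 at `n = h`, strictly decreasing.
Counts are pooled over reference groups (total records per cell), with a
per-group option; a min-max rescaled copy is kept alongside the raw values
for cross-map summary tables. The exact published form of the index was not
available, so the standard half-saturation form matching the "half" naming
and the "inverse of the number of occurrences" description is implemented,
with `h` configurable.

**Bhattacharyya distance** normalizes both maps to densities over shared
valid cells and returns `−ln Σ √(pq)`; identical maps give 0, disjoint
support gives `inf`.

## Validation scenarios (`experiments`)

Two canned experiments define the package's standard self-checks; their
constants are study conditions, fixed here and not per-run dials.

*Parameter recovery.* A rare, strong-signal specialist: |β| = 2 on each of
three climate predictors, prevalence calibrated to 0.05, 900 sampled
records (~420–500 presence cells) on a 64×64 world, ensemble of
glm+fda × 3 pseudo-absence sets × 2 CV runs against 2 000 pseudo-absences.
The 64×64 world is the smallest power-of-two lattice on which ~500 presence
cells plus 2 000 pseudo-absence cells can be drawn without replacement. The
low prevalence matters scientifically: at prevalence ~0.1 the truth
surface's *own* best achievable TSS against background cells is only ~0.73,
so "the model recovers the niche" and "TSS ≥ 0.7" would conflate model
error with an intrinsic ceiling; at 0.05 the ceiling is comfortably higher
and TSS measures recovery. Recovered binary ranges are compared with the
truth binarized by the *same* TSS-maximizing rule on the same data — truth
and estimate under one binarization convention — via Jaccard overlap.

*Hierarchy nesting.* A species whose habitat term is a pure constraint
(negative quadratic, γ = −2: it can only reduce suitability below the
climate-only level), prevalence 0.1, with the 32×32 study region sited over
the most climatically favorable window of the world
(`climatically_favorable_region`). Both choices encode the premise of the
two-tier design rather than tuning: a habitat descriptor that *limits* an
otherwise climatically suitable range is exactly the case the regional tier
exists for, and an invaded study region is, by construction, broadly
climatically suitable — with an arbitrary region the climate-only and
regional areas are statistically exchangeable and no nesting should be
expected. Replicates with too few regional presence cells to model are
skipped exactly as the pipeline skips unmodellable species.

## Problem sizes

Defaults in tests, examples and the reproduction script use 40×40–64×64
grids, 600–2 000 pseudo-absences, rosters of 2–3 algorithms and 2 CV runs —
sizes chosen so a complete validation cycle runs in well under a minute on
one CPU while every code path (variant tagging, VIF removal, fallback
selection, weighting, zoning, uncertainty) is exercised. Full-scale
defaults (5 algorithms × 3 sets × 4 runs = 60 models, 20 000/5 000
pseudo-absences) remain the `EnsembleSettings` defaults.

## Known limitations

* The learner roster matches the published algorithm *families*, not any
  specific R implementation's numerics; member-level agreement with other
  SDM frameworks is out of scope.
* The equirectangular exclusion-point distance degrades near the poles.
* The committee CV rescaling divides by the map maximum, so CV values are
  comparable within a map but not across species with different maxima
  (the mean-CV zoning input inherits this convention).
* MESS with very small reference sets (< ~20 points) is noisy; the package
  does not warn below a sample-size floor.
* The synthetic world is stationary and additive; none of the validation
  results speak to niche shifts between native and invaded ranges, the very
  phenomenon that motivates using both ranges in the global tier.
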