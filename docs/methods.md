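# Methods

## The model

`maxhab` estimates relative habitat suitability from presence-only records
and raster covariates with a maximum-entropy (maxent) presence-background
model.  Among all probability distributions `p` over the landscape's cells,
the estimator seeks the one closest to uniform (maximum entropy) whose
feature expectations match the presence sample, softened by an L1 penalty.
Equivalently it is an L1-regularized Gibbs / log-linear density: with
feature vector `f(x)` and weights `λ`, the fit maximizes

    J(λ) = (1/n) Σ_presence λ·f(x_i) − ln Z(λ) − Σ_j rm·β_j·|λ_j|,
    Z(λ) = Σ_background exp(λ·f(x)).

The stationarity (KKT) conditions are the maxent moment constraints with a
tolerance band: every feature with a nonzero weight matches its presence
mean to exactly `rm·β_j`; features inside the band stay at zero.  This is
asserted on fitted models in the test suite (tolerance 1e-4).

**Outputs.**  The *raw* output `exp(λ·f(x))/Z` is the fitted distribution
over the background sample (sums to one there).  The *cloglog* output
`1 − exp(−e^H · raw)` with `H` the entropy of the fitted background
distribution rescales raw scores into (0, 1); we report it as relative
suitability (0 low, 1 high), not occupancy probability.

**Features.**  Continuous covariates expand per the configured feature
class: `L` linear, `Q` quadratic, `H` forward hinges
`max(0, (x−k)/(max−k))` at 50 knots placed at uniform background quantiles
(knot count configurable).  Categorical covariates always expand to one
indicator per observed class.  All features are min-max normalized on the
background sample and clamped to [0, 1] — during training as well as
prediction, which guarantees every one-dimensional subproblem in the
optimizer has a finite solution under any positive penalty.

*Quadratic parameterization.*  Squares are centered on the background mean,
`(x − x̄_bg)²`, rather than raw `x²`.  The spanned function space
{1, x, x²} is identical, but for a covariate whose spread is small relative
to its magnitude (e.g. a temperature normal of 12.3 ± 1.5 °C) the raw
square correlates with the linear feature at ρ ≈ 0.999; a peaked response
then requires an opposing weight pair two orders of magnitude larger than
the centered parameterization needs, and coordinate-wise optimization
stalls at rate 1−ρ².  Centering is purely a conditioning choice; it changes
which functions the L1 penalty prefers only insofar as it makes peaked
responses no more expensive than monotone ones.

**Default penalties.**  `β_j` defaults to the published
reference-implementation schedule: a feature-kind constant interpolated in
presence sample size (linear 1.0→0.05 over n 10→100; quadratic 1.3→0.5 over
0→17; hinge 0.5; categorical 0.65→0.25 over 0→17), scaled by the feature's
presence-sample SD over √n and floored at 1e-4.  The grid multiplier `rm`
(0.5, 1, 2, 5 by default) scales all of them.  Invariant tests pass
explicit betas so they do not depend on this schedule.

**Optimizer.**  Cyclic coordinate ascent with exact one-dimensional line
search: each sweep scans all KKT violations with one matrix product, then
solves each violating coordinate's penalized subproblem exactly (bracketed
Brent root of the orthant-wise derivative; the soft-threshold case `λ_j=0`
is detected analytically).  The penalized objective is asserted
non-decreasing every sweep.  Convergence requires both an objective
improvement below `tol` (1e-5) and a maximum KKT violation below `kkt_tol`
(1e-5); the cap is 3000 sweeps (models returned flagged if hit — late
sweeps are cheap because only violating coordinates are touched).  Weights
are capped at ±50, reachable only under separation with a vanishing
penalty.  Percent contribution credits each coordinate update's absolute
objective change to the feature's source variable; it is path-dependent by
construction, and reproducible because the update order is the fixed
feature order.

## Evaluation and selection

* **AUC** is the rank-based (Mann–Whitney) probability that a random
  presence outscores a random background point, ties counted ½.
* **10% omission**: the threshold is the smallest training score with ≥90%
  of training scores at or above it (drop the lowest ⌊0.1·n⌋); omission is
  the fraction of held-out scores strictly below it.  With n < 10 training
  scores the minimum is used, with a warning.
* **Jackknife CV** leaves one presence out per fold on a shared background;
  per fold it records training AUC, the held-out point's validation AUC,
  and a 0/1 omission.  `auc_diff_avg` is the mean train−validation AUC;
  `or10_sd` uses the sample (n−1) denominator.  A `max_folds` cap (a seeded
  subset of presences serving as hold-outs) keeps large grids tractable;
  the cap is off by default.
* **AICc** uses the presence log-likelihood under the raw distribution
  standardized over the background sample (the prediction-domain stand-in;
  swap in a full-raster domain by scoring all cells), with k = the count of
  nonzero weights; undefined when n − k − 1 ≤ 0.
* **Stepwise selection**: keep the ⌈m/2⌉ configurations with lowest mean
  omission (ties broken by lower AUC difference, then lower AICc); keep
  those strictly below the survivors' median AUC difference (all kept if
  none are strictly below); choose the minimum defined AICc.  Summaries
  with non-finite statistics are excluded before step 1.  ΔAICc is always
  computed against the *full-grid* minimum, so a selected model can have
  ΔAICc > 0.

A note on published "SD OR 10%" columns: printed values above 4 cannot be
the SD of a rate bounded by one; their scale is unexplained in the source
table.  This package reports the across-fold sample SD and makes no attempt
to reverse-engineer that scale.

## Bootstrap uncertainty and importance

Ten replicates (default) each refit the selected configuration on
⌊0.8·n⌋ presences drawn *without* replacement — the literal reading of
"80% of the presence data"; a classical with-replacement draw is available
behind the `replace=True` flag — and predict a cloglog surface.  Cellwise mean/min/max/range across
converged replicates give the suitability and uncertainty maps.
Permutation importance shuffles one covariate across all training rows
(categorical labels move whole), re-scores without refitting, floors
negative training-AUC drops at zero, and normalizes to percents; one
permutation per variable per replicate.  Percent contribution and
permutation importance are reported as across-replicate means.

## The virtual landscape

The generator produces the statistical structure the analysis assumes, on a
desk-size domain (400×400 cells of 5 m, i.e. 2×2 km, by default):

* **Geology**: an additively-weighted Voronoi (power diagram) mosaic of ~24
  seeded patches; cells are convex, hence each class is one 4-connected
  region.  The first seed's weight is calibrated by bisection so the
  largest class covers the requested area fraction (default 0.29).
* **Elevation**: Gaussian-filtered white noise (correlation length 400 m)
  rescaled to span 2200–3100 m; slope and curvature derive from it with the
  package's own Horn-gradient operators; distance-to-contact derives from
  the geology mosaic.
* **Climate**: five seasonal normals simulated on a 16× coarser grid as
  Gaussian-smoothed noise (correlation length 200 m), bilinearly
  downscaled, then affinely calibrated so each layer's fine-grid mean and
  spatial SD equal the requested normal exactly.  Defaults: summer/winter
  precipitation 354/289 mm (annual total 643 mm), winter max 12.3 °C,
  winter min −2.4 °C, summer min 4.6 °C, spatial SDs 1.2–35 in natural
  units.  The coarseness factor and correlation length are scaled-down
  analogues: a full-size mountain study area has on the order of 40
  climate cells across its extent and seasonal normals decorrelating over
  a small fraction of the domain, and preserving those ratios — rather
  than the raw 800 m / 5 m resolution ratio — is what keeps the climate
  layers mutually distinguishable, hence the truth recoverable, on a small
  grid.  With the raw ratio the five climate layers would each be a
  near-planar field interpolated from a 3×3 coarse grid; independent
  near-planar fields are strongly correlated by chance, and no method can
  attribute importance among them.
* **Truth**: log-linear in geology (four mid-frequency favored classes at
  offset +2.0, giving occupancy ratios ≥ 3), a dominant negative quadratic
  in winter maximum temperature (−2.4 per squared SD), and a weak positive
  linear term in winter minimum temperature (+0.4).  `truth_raw` is the
  normalized exponential over cells.
* **Presences**: weighted draws from `truth_raw` — without replacement by
  default (Gumbel top-k; matches the one-record-per-pixel dedup downstream)
  or with replacement for frequency-recovery checks.  Coordinate error
  jitters each record uniformly within a disk whose radius is drawn from a
  user list; the error distribution of real archival records is unknown,
  and the uniform disk is this package's choice.

What the generator does *not* emulate: fire history, vegetation, soils,
anisotropy, sampling bias fields, or any geologic process realism beyond
contiguity.  Passing tests on these landscapes demonstrate that the
pipeline recovers known structure under its own assumptions — not that any
particular real dataset satisfies those assumptions.

## Pipeline conventions

Rasters use upper-left-origin, row-major grids with half-open cell
intervals (`cell = floor((coord − origin)/cell_size)`); all distances are
planar Euclidean on projected meters.  ESRI ASCII grids are the primary
interchange format (GeoTIFF via pixel-scale/tiepoint tags is also
supported); reprojection is out of scope — inputs must share a projection.
Deduplication keeps the first record per pixel by input order.  Point
records are thinned *first* and error windows expanded afterwards (the
half-width is ⌈error/(2·cell)⌉, so a 10 m error on a 5 m grid marks a 3×3
block); the reverse order is equally defensible and not what this package
does.  Climate downscaling is plain bilinear with nearest-edge
extrapolation, isolated behind one function so a different scheme can be
swapped in.  One master seed spawns named substreams (thinning, error,
background, grid, replicates), so any stage re-run in isolation reproduces
its outputs; the manifest records all of them.

## Problem sizes

The default test-suite landscapes are 64–150 cells square with hundreds to
a few thousand background points; the parameter-recovery experiment runs
the full default conditions (400×400 cells, 189 presences, 10,000
background points, 10 replicates, 10 landscape seeds).  The acceptance
script's end-to-end run uses a 200×200 landscape, 250 pre-thinning
presences, 5,000 background points, a 15-fold CV cap, and the full
16-configuration grid — sizes chosen to exercise every stage at realistic
sample-size ratios on a single CPU.

## Known limitations

* Product and threshold features are out of scope by design; reverse
  hinges are not implemented (forward hinges only).
* Percent contribution is path-dependent (as in the reference
  implementation) and should be read qualitatively; permutation importance
  is the more stable measure.
* AICc's prediction domain is the background sample, which biases the
  normalization when the background under-covers the landscape.
* The thinning algorithm is stochastic and returns a maximal replicate, not
  a certified maximum independent set; on small instances (≤12 points) it
  matches exhaustive search across many replicates in the test suite.
* Extrapolation beyond the training background range is clamped, not
  flagged (no MESS-style novelty diagnostics).
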