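# Methods

`forestdrivers` analyzes what drives deforestation and reforestation on a
regular analysis grid. It combines four stages: remote-sensing change
products, dasymetric population mapping, geographically weighted random
forests (GWRF), and a cluster-and-test driver assessment. This note
documents the models, the parameters that matter, the synthetic data the
tests rely on, and the numerical choices made where the design was open.

## Forest-change products

**Annual change rate.** Forest area per 400-ha grid cell at two census
years gives the FAO compound annual rate

    q = (A2 / A1)^(1 / (t2 - t1)) - 1

Loss is negative (`A2 < A1 => q < 0`); reporting layers may take absolute
values for readability, but stored rates keep their sign. Cells with
`A1 = 0` are undefined and returned as missing with a logged count.

**Patch filtering.** Change patches below 1 ha are cleared before rate
calculation, since isolated small patches are usually classification
noise. Connectivity is 8-neighbor (queen) by default — the common
remote-sensing convention — and switchable to 4-neighbor. The operation is
idempotent.

**Land-cover frequency.** For a pixel with a change event at date *i* in
an *n*-date categorical stack, the frequency of class *Z* is the percent
of dates *Z* occupies in the after-segment (dates *i..n*, deforestation)
or the before-segment (dates *1..i-1*, reforestation). A before-segment at
the first date is empty and rejected. A validator checks the upstream
convention that reforestation events persist as forest for at least 4
years; event detection itself is out of scope.

**Pixel trends.** Per-pixel OLS slope of value against year (at least 3
dates; at least 2 finite values per pixel), matching the closed form
`sum((x - x̄)(y - ȳ)) / sum((x - x̄)^2)` to 1e-10.

**Grid extraction.** Pixels belong to the analysis cell containing their
center; continuous layers aggregate as means, categorical layers as
per-class areas. Layers must share a CRS tag — there is no silent
reprojection anywhere in the package.

## Dasymetric mapping

Census-block populations are redistributed over a 1-ha grid using rural
density classes: travel time to roads reclassified as high [0, 1) h,
medium [1, 3) h, low [3, inf) h, intersected with a non-forest mask
(half-open, left-closed intervals for determinism at the boundaries).
Exactly three classes are supported; the scheme is untested beyond three
and the validator enforces it.

Density fractions come from census blocks lying almost completely within
one class — operationalized as >= 95 % of a block's classed cells in a
single class (configurable; no published threshold exists). With class
densities `p_u = population / area`:

    d_u = p_u / (p_high + p_medium + p_low)

Fractions are averaged across census years before allocation (per-year
mode is available). Within each block, the area ratio
`a_u = (n_u / n_b) / 0.33` uses the constant 0.33 exactly as the scheme
defines it (not 1/3; configurable). The total fraction renormalizes
`d_u * a_u` over the classes present, and each class's share spreads
evenly over its cells:

    pop_cell = f_u * pop_b / n_u

This conserves every block total by construction (the pycnophylactic
property); `pycnophylactic_check` verifies it per block to a 1e-6
tolerance, rescaling clipped blocks proportional to their original areas.
Unallocatable blocks (no classed cells) are reported, never dropped
silently. Intercensal change is a cellwise subtraction of two aligned
surfaces.

## Geographically weighted random forest

At each location *i*, a local random forest is trained on the kernel
neighborhood of *i*, with exponential kernel weights
`w_j = exp(-d_ij / bw)` used as bootstrap sampling probabilities
(case-weighted bagging). The adaptive kernel takes the `K_bw` nearest
observations (the location itself included, weight 1); the distance scale
of the kernel is the distance to the `K_bw`-th neighbor — the GWmodel
convention. Distance ties at the cutoff break by observation index so
results are deterministic.

Per-location fitting:

1. drop covariates with zero local variance;
2. classification only: upsample minority classes to the local majority
   count (resampled rows keep their kernel weights);
3. train a case-weighted forest (defaults: 500 trees, `mtry = floor(sqrt(p))`
   features per node, unpruned trees, min leaf 1 for classification and 5
   for regression — the ranger-style calibration);
4. compute out-of-bag (OOB) permutation importance; remove covariates
   with negative importance; if any were removed, retrain once and remove
   negatives again (never a third pass);
5. re-enter removed covariates with importance 0, so every location's
   local variable importance (LVI) vector covers the full covariate set —
   a requirement for clustering the surfaces later;
6. extract the OOB prediction at *i* (class probabilities or value) and
   neighborhood-level OOB accuracy: kappa and prediction failure
   (1 - OOB accuracy) for classification, R-squared and residual standard
   error (n-1 denominator) for regression.

Locations whose dependent variable is single-valued in the neighborhood
are skipped with a logged reason, not imputed. Per-location RNG
substreams derive from the master seed and the location index, so serial
and parallel execution agree.

**Honest OOB under upsampling.** Upsampling duplicates minority rows; with
naive bookkeeping a duplicate can sit in a tree's bag while its twin is
scored "out-of-bag", which inflates OOB accuracy — most strongly at small
bandwidths where local class imbalance is severe. In our experiments this
leakage was large enough to invert the bandwidth-accuracy relationship
entirely. The forest engine therefore accepts a `groups` vector tying
duplicates to their source row: an observation is OOB for a tree only
when no member of its group was drawn. The GWRF loop always uses it.

**Rate reclassification.** For classification runs, continuous rates are
discretized into 5 ordered classes, by quantile breaks by default
(balanced classes help local fitting; no canonical break set exists) or
by user-supplied fixed breaks. Deforestation-style rates are classified
on absolute values; the sign stays in the stored data.
Accessibility/distance covariates can be min-max normalized to 0-1 and
inverted (flagged per variable in the configuration) so that larger
always means more accessible.

**Bandwidth selection.** `bandwidth_sweep` refits the surfaces over a grid
of adaptive bandwidths and summarizes location-level kappa (or
R-squared) as mean ± SD; the recommended bandwidth is the smallest whose
mean lies within one SD of the best. On stationary data more neighbors
simply mean more training data, and kappa rises with bandwidth toward a
plateau. On strongly non-stationary data (distinct regional regimes)
large kernels mix regimes and accuracy can fall instead — both behaviors
are real, and the test suite exercises the stationary one.

## Driver assessment

LVI surfaces from two runs (deforestation-like and reforestation-like)
are each clustered with a Gaussian mixture fitted by EM (full
covariances, 1e-6 diagonal regularization, up to 5 seeded restarts on
non-convergence). The number of clusters, when not fixed, comes from the
gap statistic over k = 1..6 against 50 uniform reference draws, using
the standard one-standard-error rule (smallest k with
`Gap(k) >= Gap(k+1) - s(k+1)`). LVI vectors are clustered raw by
default; z-scoring is a flag. The cluster with the highest mean
dependent rate is selected as the active change front; overlap between
the two runs' selected clusters is reported, not resolved.

Per variable, the two selected clusters are compared with the two-sided
Wilcoxon rank-sum test (exact distribution for n + m <= 20 without ties,
normal approximation with continuity and tie corrections otherwise) and
Cliff's delta `d = (#{x>y} - #{x<y}) / (nm)` with the published Romano
magnitude cut-offs: negligible |d| < 0.147, small < 0.33, medium
< 0.474, large otherwise. Categories: *equal* when p >= 0.05 or the
median difference is zero; otherwise *greater* / *lower* by the sign of
the median difference. No multiple-testing correction is applied by
default — a deliberate, documented limitation; Holm adjustment is
selectable and can only move variables toward *equal*.

## Synthetic data

No study rasters or census microdata are deposited, so the generators
produce every input with known ground truth:

- **Spatial datasets**: a square grid of 400-ha cells (2000 m spacing,
  projected meters); i.i.d. standard-normal covariates; the response in
  each rectangular region is a linear combination of that region's
  active covariates plus Gaussian noise. The canonical benchmark has two
  regions (west driven by x1, east by x2, effect 2.0, noise SD 0.5) —
  strong but not noiseless regional signals. The region map and active
  covariates are returned as ground truth.
- **Land-cover stacks**: constant-class pixels except planted events
  that switch forest to pasture at a known date, making every frequency
  product computable in closed form.
- **Census fixtures**: a three-band density-class raster at 1-ha pixels
  with non-overlapping rectangular blocks — one pure block per class
  (so class densities are sampleable) plus straddling blocks — with
  Poisson populations around class target densities of 0.010 / 0.008 /
  0.002 persons/ha (rural orders of magnitude), and true per-class cell
  counts per block.

What the synthetic data does *not* emulate: spatially autocorrelated
covariates, spectral or classification noise, irregular block geometries,
and real settlement patterns. Passing tests therefore demonstrate that
the algorithms recover planted structure under their own assumptions, not
that the pipeline's conclusions hold on any particular real landscape.

## Problem sizes used by the test suite

Simulation-based checks run at desk scale, chosen to keep each property
comfortably resolvable: importance recovery on the 900-cell two-region
benchmark with bandwidth 100 and 60-tree local forests; the
bandwidth-accuracy trend on a 441-cell stationary fixture over bandwidths
{50, 100, 200, 400} with 30-tree forests; the weighted-bagging contract
over 100,000 bootstrap draws; the global-bandwidth consistency check on a
144-cell fixture with 100 trees and permutation importance averaged over
2 repeats. Production runs would typically use the 500-tree default.

## Known limitations

- Euclidean distances only; no network or great-circle kernels, and only
  the exponential kernel function.
- The linear GWR estimator and mixed global/local models are out of
  scope, as are partial-dependence diagnostics.
- OOB kappa of local models is an internal estimate; with heavy
  upsampling its effective sample is the balanced (not the observed)
  class distribution.
- The gap statistic with GMM labels on near-degenerate LVI surfaces can
  be unstable; identical rows short-circuit to a single cluster.
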