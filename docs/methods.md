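# Methods

## Scope and model family

The package implements presence-only habitat-suitability modelling with two
classical profile methods — a climatic envelope (BIOCLIM) and a
nearest-record Gower similarity (DOMAIN) — plus the surrounding pipeline:
occurrence thinning, collinearity pruning, PCA diagnostics, replicated
AUC validation, six-level classification, and current-vs-future scenario
accounting. Both models use presences only; background cells enter solely
through validation. Neither model estimates occurrence probability: BIOCLIM
scores percentile typicality inside the observed climatic envelope, DOMAIN
scores climatic proximity to the most similar training record.

## The BIOCLIM suitability index

The index is computed per variable as the mid-rank percentile
`p = (#{train < x} + 0.5 · #{train = x}) / n` and folded into the tail score
`min(p, 1 − p)`; the site score is `100 × min over variables` of the tail
scores, and exactly 0 when any variable falls outside the training min–max.
The classical envelope software popularized the six-band legend used here
(with the top band ending near 41 rather than the theoretical 50 — a finite
training sample rarely places a cell exactly at every median) without
printing the index formula, so this two-tailed percentile reconstruction is
the one inferential step in the package. It is deliberately the simplest
definition consistent with the banding geometry: scores in [0, 50], maximal
at the joint training median, 0 outside the envelope. No clamp is applied at
41; that value is an observed maximum of a particular run, not part of the
algorithm.

Choices that follow from the definition:

- **Band edges are upper-inclusive** — (0, 2.5] low, (2.5, 5] medium,
  (5, 10] high, (10, 20] very high, > 20 excellent — so the chained printed
  ranges partition without overlap; a score of exactly 0 is its own
  "unsuitable" class.
- **A constant training variable** contributes tail score 0.5 when the site
  matches the constant and puts the site out of the envelope otherwise;
  both fall out of the mid-rank formula with no special-casing.

## The DOMAIN similarity

Gower distance with equal variable weights, ranges computed from the
*training points only* (not the whole grid), similarity
`100 × (1 − min over training points of the distance)` — the standard
single-nearest-record variant rather than a mean over k best matches. No
flooring is applied: deeply negative similarities simply mean "far outside
the training cloud", and the classification maps everything below 90 to
unsuitable anyway. Thresholds are lower-inclusive: [90, 92) low … [96, 98)
very high, ≥ 98 excellent. A zero training range (constant variable)
contributes 0 on an exact match and 1 otherwise — the limit of |Δ|/r as the
spread collapses. The grid scan over training points is exact, chunked over
cells only to bound memory; no spatial index is needed at the grid sizes the
package targets.

## Variable diagnostics

- **Descriptive statistics** report sample SD (n − 1), CV = 100·SD/|mean|
  (undefined marker when the mean is exactly 0 with positive spread), and a
  normal-approximation 95% CI (z = 1.96), which reproduces the reporting
  convention of the descriptive tables this pipeline emits (Student-t at
  n ≈ 600 is indistinguishable at one decimal). Tables round
  half-away-from-zero to one decimal.
- **Stepwise VIF pruning** regresses each variable on the remaining ones
  (with intercept, via ordinary least squares) and drops the largest-VIF
  variable while any VIF ≥ 5, the conventional collinearity cutoff.
  Numerically perfect collinearity (R² within 1e−12 of 1) is assigned the
  finite sentinel 1e12 so the greedy loop stays total; ties on the maximal
  VIF drop the later column, which makes the procedure deterministic under
  a user-visible ordering.
- **PCA** eigendecomposes the correlation matrix by default because the
  variables mix units (°C, mm, dimensionless seasonality); covariance PCA is
  available for pre-standardized inputs. Components are sorted by descending
  eigenvalue, and each loading column is signed so its largest-magnitude
  entry is positive. The PCA accepts an explicit variable subset — it makes
  no attempt to decide which variables a given study fed it.

## Validation protocol

Each replicate draws a fresh random 70/30 train/validation split (train size
= n × 0.7 rounded half away from zero, so 604 records give 423/181), fits
the model on the training presences, and computes the AUC of the validation
presences against a background sample. Because the protocol details of
presence-only AUC are rarely printed, the package makes its own explicit:
background cells are sampled uniformly at random from non-nodata cells
excluding *all* presence cells, with a default size of 10 × the number of
test presences (capped by the number of eligible cells, and always logged in
the report). Replicate r derives its randomness from `seed + r`, so
individual replicates can be reproduced in isolation. The AUC is the
Mann–Whitney U statistic divided by the product of the two sample sizes
(mid-rank ties), and the summary is the mean ± sample SD over replicates.
The final suitability surface is the cellwise mean of the replicate score
grids, for both the current and (with the same fitted models) the future
stack.

## Scenario change accounting

Cell areas use the spherical-band formula on the authalic sphere
(R = 6371.0072 km): `R² · Δλ · (sin φ_top − sin φ_bottom)`, which gives
21.47 km² for a 2.5′ cell on the equator and decays as cos φ. Class areas
are reported in 10⁴ km², percent change as
`100 × (future − current)/current` rounded half away from zero to one
decimal (a class absent now but present later gets an undefined-change
marker rather than a number). The transition map labels each cell of the
focal class (default "excellent") as retained/lost/new, satisfying
`retained + lost = current count` and `retained + new = future count`.
Patch statistics use 4-connectivity by default (8 available); fragmentation
is summarized as patch count, mean and maximum patch size in cells.
Land/sea masking is whatever nodata mask the input stack carries — the
package ships no coastlines, so absolute area totals on real data depend on
the user's own mask.

## The synthetic study

`synthgrid` generates, per variable, a standard-normal field that is
cross-correlated across variables by a symmetric square-root factor of the
target correlation matrix (eigenvalue factorization, tolerant of singular
PSD matrices such as perfect correlation), then spatially smoothed by a
uniform moving average of configurable radius with edge-truncated windows.
Because the pre-smoothing cells are spatially independent, the smoothed
field is rescaled by √(window size) per cell, restoring exact unit marginal
variance while keeping the induced spatial autocorrelation; layer values are
then `mean + sd × field`. Occurrences are drawn without replacement at cell
centers with probability proportional to an envelope weight (inside weight
1, outside 0 by default), and each record stores the environmental values of
its generating cell so extraction can be verified exactly.

Defaults describe the modelled-variable set of the motivating study system:
six variables (bio6, bio8, bio10, bio11, bio12, bio13) on a 120×120 grid at
2.5′, with means/SDs matching the descriptive statistics of the occurrence
region (bio6 −1.7 ± 4.0 °C, bio8 23.6 ± 2.5, bio10 25.3 ± 1.9,
bio11 3.6 ± 3.3, bio12 1113.2 ± 369.4 mm; bio13, for which no table row
exists, uses 200 ± 70 mm, a realistic wettest-month share of ~1100 mm annual
precipitation). The default cross-correlation matrix couples the winter
temperatures (bio6–bio11 at 0.85) and the precipitation pair (bio12–bio13 at
0.8) with moderate cross terms; it is positive-definite and implies VIFs of
1.6–3.8, so the VIF step keeps all six variables under default conditions.
The default true envelope is the ±0.8 SD box around each mean (≈9% of
cells), 604 presence points are drawn, and the future scenario adds
+3.5/+3.2/+3.8/+3.6 °C to the temperature variables and +90/+15 mm to the
precipitation variables — a plausible doubled-CO₂ end-of-century signal.
Synthetic occurrence elevations (attached by `simulate_command` for the
altitudinal summary) are gamma(2, 350)-distributed, i.e. right-skewed with
mean 700 m, mimicking a low-elevation-dominated record set; they are
plumbing for the summary stage, not part of the suitability models.

**What the generator does and does not emulate.** It reproduces the
features the pipeline is sensitive to — smooth inter-correlated layers with
realistic means and spreads, presences confined to a known envelope, a
uniform additive climate shift — but not topography, coastlines, anisotropic
climate gradients, sampling bias, or spatially structured occurrence error.
Passing tests therefore demonstrate algorithmic correctness and recovery of
a known truth, not predictive skill on real rasters. Two desk-scale
artifacts are worth naming: (i) the 120×120 domain at 2.5′ spans only ~5°,
so the spatial climate gradient is compressed relative to a continental
study area, and the default future shift (≈1–2 SD of the temperature
variables) pushes most of the envelope off the grid — the demo's severe
excellent-habitat contraction is a property of that compression, not a
calibrated projection; (ii) with outside weight 0 the sampler is a hard
truncation, so envelope recovery is exact by construction and is a test of
bookkeeping, not of statistical efficiency.

## Numerical choices and degenerate inputs

- Rounding of reported percentages and table values is half-away-from-zero
  (`17.4545 → 17.5`, `−0.9176 → −0.9`), implemented once in `_util`.
- Grid cell lookup is floor arithmetic from the north-west origin; points on
  a cell's western/northern edge belong to that cell, the eastern/southern
  grid boundary is exclusive.
- Thinning keeps the first record per cell in input order; it is idempotent.
- Altitude classes are lower-inclusive half-open bins (800 m counts as
  "mid"); records lacking elevation stay in the modelling set and are
  excluded only from the altitude summary.
- AUC banding and DOMAIN thresholds are lower-inclusive; BIOCLIM bands are
  upper-inclusive (see above). Probes at the printed edges are pinned in the
  test suite.
- `make_future_stack` is strictly additive per layer and preserves the
  nodata mask; scenario comparison refuses grids whose georeference or mask
  differ.
- Rasters are ESRI ASCII grids (text); values round-trip at `%.6g`
  precision, which the stack-reading tests account for.

## Problem sizes

The shipped analysis and the acceptance script run the full default
scenario: 120×120 cells × 6 variables, 604 presences, k = 10 replicate
splits per model, background 10 × test presences (1810) or 500 for the null
check. The complete chain runs in a few seconds on one CPU; the test suite
uses an 80×80 variant of the same scenario for its session fixtures.

## Known limitations

- The BIOCLIM index is a reconstruction (above); other implementations may
  use one-tailed percentiles or clamp differently, so absolute scores are
  comparable only within this package, though the band geometry matches the
  published legend.
- DOMAIN uses the single nearest record; the mean-of-k-best variant and
  weighted Gower are out of scope.
- No administrative-boundary thinning (per-cell thinning approximates it),
  no interpatch-distance or centroid-shift statistics, no map rendering, and
  no climate-data download adapters.
- Real-data area totals depend on the user's land mask; the package makes no
  attempt to reproduce any published absolute areas, only the arithmetic
  that relates them.
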