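# Methods

This note documents the models and procedures implemented in `avistack`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic validation does and does not demonstrate.

## The modelling framework

`avistack` implements a stacked species distribution modelling (S-SDM)
workflow for presence-only data. For each species, presence records and a
background sample of landscape cells are used to fit a maximum-entropy
niche model; the continuous suitability surface is binarized at a
per-species threshold; binary maps are summed cell-wise into species
richness; richness is classified into moderate / sub-hotspot / hotspot
levels by natural breaks; and hotspot classes are overlaid with a
protected-area mask to quantify protection gaps.

### The maximum-entropy niche model

The core model is a Gibbs (log-linear) distribution over the background
cells,

    P(x) = exp(λ · f(x)) / Z,     Z = Σ_background exp(λ · f(x)),

whose coefficients maximize the penalized presence log-likelihood

    J(λ) = mean_presence[λ · f(x)] − log Z(λ) − Σ_j β_j |λ_j|.

This is the standard presence-background maximum-entropy formulation: among
all distributions whose feature expectations match the presence sample
within the β-tolerances, it selects the one of maximum entropy. Features
f(x) are built per environmental variable after rescaling to [0, 1] over the
background range: linear (L), quadratic (Q), pairwise products (P), forward
and reverse hinges (H) and step thresholds (T) at 10 knots placed at equally
spaced background quantiles, plus one indicator per class of any categorical
variable. All features map into [0, 1]; prediction-time values outside the
training range are clamped to it (the count of clamped values is reported as
a diagnostic) rather than extrapolated.

Per-feature penalties follow the defaults of the widely used reference
implementation: a feature-class base penalty interpolated in the presence
sample size m (e.g. linear features interpolate 1.0 → 0.2 → 0.05 over
m = 10 → 30 → 100; hinges use a constant 0.5), scaled by the feature's
presence-sample standard deviation over √m, and multiplied by the
user-facing regularization multiplier (RM). A small floor (sd ≥ 1e-3) keeps
penalties positive for features that are constant at the presences.

The objective is kept in per-presence-mean form; together with the √m
scaling of β this matches the convention of the reference software. The
model-selection log-likelihood (below) uses the sum over presences of the
log normalized raw probability, which is the scale on which AICc is defined.

**Optimizer.** Cyclic coordinate ascent with soft-thresholding: for each
coordinate a prox-Newton step λ_j ← S(λ_j + g/h, β_j/h) is proposed (g the
smooth gradient, h the background variance of the feature, S the
soft-threshold operator) and backtracked against the exact objective so the
penalized objective is non-decreasing. A cycle's objective change below
`tol` (default 1e-5) or `max_iter` cycles (default 1000) stops the fit;
which one fired is recorded. The exact objective evaluation per update makes
the fitter verifiably optimal: on micro-instances its solution attains the
optimum of a dense coefficient grid to 1e-6, and on one-feature problems it
matches 1-D grid search to 1e-3.

**Output scales.** Raw probabilities sum to 1 over the background. With H
the entropy of the fitted background distribution, the logistic output is
q = e^H r / (1 + e^H r) and the cloglog output q = 1 − exp(−e^H r). Both are
monotone in r, so cell rankings are identical on all scales. Logistic is the
default, and the binarization stage operates on it.

**Variable contributions.** Permutation importance: a variable's raw values
are permuted jointly across the pooled presence and background cells (all
features derived from it move together), the drop in training gain under the
fixed coefficients is averaged over permutations, floored at zero and
rescaled to sum to 100%.

### Model selection

Candidates are feature combinations (default L, LQ, LQH, LQHP, LQHPT, H)
crossed with RM values (default 0.5-4.0 in steps of 0.5). Each candidate is
scored by k-fold cross-validation (default k = 10): the omission threshold
is the 10th percentile of training-presence suitability and a held-out
presence scoring strictly below it is omitted. Candidates with mean test
omission below the cap (default 0.05) form the feasible set; among them the
minimum-AICc candidate is selected, with

    AICc = 2K − 2 lnL + 2K(K+1)/(n − K − 1),

computed on a final fit to all records, K the number of non-zero
coefficients and lnL the summed log normalized raw probability at the
presences. Ties break toward smaller K, then smaller RM, then grid order;
candidates with n − K − 1 ≤ 0 are flagged invalid. If no candidate meets the
cap, the lowest-omission candidate is selected and flagged.

Note that the 10th-percentile omission statistic has an expected held-out
omission near 0.10 by construction, so a 0.05 cap is demanding; on the
synthetic communities the fallback path is therefore the common case, and
the `feasible` flag in the results records which path was taken. Test
omission (not training omission) is used, and cross-validation partitions
are random rather than spatially structured.

### Evaluation

AUC is presence-versus-background — the probability a random presence
outranks a random background cell, ties counting ½ (rank-sum formulation) —
because no true absences exist in this framework. Its ceiling therefore
depends on species prevalence: a species occupying half the landscape cannot
score much above 0.68 even with a perfect model, while low-prevalence
species can approach 0.9+. TSS = sensitivity + specificity − 1 is reported
at the threshold maximizing sensitivity + specificity (ties resolved to the
lowest threshold), and qualitative AUC bands follow the Swets scale with
half-open intervals: excellent (0.9, 1.0], good (0.8, 0.9], fair (0.7,
0.8], poor (0.6, 0.7], fail at or below 0.6.

### Stacking, hotspots, gaps

Binarization marks a cell suitable when its logistic score is ≥ the
species' threshold (default: the max-sensitivity-plus-specificity
threshold; a fixed value or the 10th-percentile training threshold are
config options, and the choice is logged per species). Richness is the
cell-wise integer sum of binary maps; subgroup surfaces restrict the roster
by trait predicates, and any full partition of the roster (residency, diet)
sums back to the total exactly.

Hotspot classes come from Fisher-Jenks natural breaks: a dynamic program
over the distinct positive richness values (weighted by multiplicity, which
is exact because equal values can never straddle a break) minimizing the
total within-class sum of squared deviations. Zero and nodata cells are
excluded. Fixed intervals can be supplied instead — e.g. the 1-99 /
100-149 / 150-182 partition used for a 312-species community — and values
above the top interval are then clipped into the top class by default
(configurable, since no convention exists for them).

Cell areas are (111.32 × cellsize_deg)² × cos(latitude at the cell's row
center) for geographic grids, or the stated area for planar grids. The gap
report tabulates, per class, total area, protected area and percentage, and
unprotected (gap) area; protected + gap = total exactly before rounding.
All printed percentages and areas round half-up to two decimals, the
convention that reproduces standard reported tables exactly. A worked-example
mode accepts (total, protected) pairs directly so published area tables can
be re-derived without rasters.

### Occurrence preparation

Cleaning removes rows with missing or non-finite coordinates, rows outside
the study extent or the observation window (default 2013-2023, inclusive at
both ends), and exact duplicates on (species, longitude, latitude, date).
Grid deduplication keeps one record per species per 2.5-arc-minute cell,
chosen uniformly at random (implemented as a seeded random priority per row,
taking the per-cell maximum). The minimum-sample rule (default 15 records)
runs after deduplication; species that fall below it only after thinning are
flagged rather than dropped, so the caller decides their fate.

Spatial thinning enforces a minimum pairwise great-circle distance
(haversine, Earth radius 6371.0088 km) per species. The search heuristic
iteratively deletes the record with the most conflicting neighbours (ties
uniform at random) over seeded restarts, keeping the largest surviving
subset; for small per-species tables (n ≤ 15) an exact maximum independent
set is also solved by branch and bound, so results are provably optimal
there. The default thin distance in the pipeline equals one model-grid cell
so that surviving records are independent at model resolution.

### Predictor screening

Pairwise Pearson correlations are computed over all valid cells (a seeded
subsample is available for very large grids). Elimination is greedy: while
any kept pair exceeds |r| > 0.7, the member of the worst offending pair with
the larger mean absolute correlation to the other kept layers is dropped
(tie: the later layer in input order). Elevation and categorical land cover
bypass screening. The kept set is guaranteed threshold-feasible, and raising
the threshold never shrinks it.

## The synthetic-data generator

The generator emulates the three input kinds the pipeline needs — an
environmental stack, presence records, and a protected-area mask — with
known ground truth:

* **Landscapes** are sums of 150 seeded Gaussian bumps (bandwidth 8% of the
  grid extent), standardized; layers after the first are blended with the
  first after empirical orthogonalization, so the realized sample
  correlation equals the requested value exactly, not just in expectation.
  The categorical layer quantile-thresholds its own smooth field into k
  classes.
* **Virtual species** apply a logistic link to a linear (optionally
  quadratic) predictor on internally standardized layers, giving an exact
  known suitability surface. The default recovery experiment uses intercept
  −4 with weight +2: a prevalence ≈ 0.07 species, chosen because real SDM
  target species are low-prevalence and because prevalence 0.5 species are
  near the presence-background AUC ceiling of ~0.68 regardless of model
  quality.
* **Records** are multinomial draws of cells proportional to suitability ×
  an optional bias surface, jittered uniformly within the cell (so
  point-to-cell assignment is exercised), with dates uniform in the default
  window.
* **Trait labels** are apportioned by largest remainder to configured
  proportions (defaults mirror a 312-species regional avifauna: 82 resident
  / 230 migratory; 196 carnivorous / 105 omnivorous / 11 herbivorous; 10
  class-I / 52 class-II national protection; 2 CR / 6 EN / 17 NT / 17 VU)
  and shuffled by seed.
* **Protected areas** are unions of random rectangles, bisected on a global
  scale factor until coverage is within ±0.02 of the target.

What this does *not* emulate: real climate fields' anisotropy and gradients,
observer-driven sampling bias structure (roads, cities), taxonomic error,
spatial autocorrelation of residual occupancy beyond the environment, and
imperfect detection. Passing tests therefore demonstrate the correctness of
the computations and the recoverability of known signal — not field
performance on real occurrence data.

## Problem sizes and numerical choices

Default experiment sizes are desk-scale by design: 40×40 to 100×100 grids
(1,600-10,000 background cells), 10-species communities, 120-250 records
per species, and reduced tuning grids (L/LQ at RM 1.0) in the end-to-end
pipeline, with the full candidate grid available through configuration.
Randomness is seeded everywhere; per-species streams derive from the master
seed plus a stable hash of the species name, so results are independent of
processing order and identical configs give checksum-identical rasters.

Degenerate inputs are handled explicitly: zero-variance layers are flagged
rather than breaking the correlation screen; an empty feature set yields the
uniform (maximum-entropy) distribution; saturated models (K ≥ n − 1) are
flagged invalid instead of producing an infinite AICc; all-equal score lists
give a defined threshold with TSS 0; species with fewer distinct positive
richness values than classes skip natural-breaks classification.

## Known limitations

* The fitter is a faithful penalized-likelihood implementation of the
  maximum-entropy model but is not a bit-for-bit replication of the Java
  reference software; no cumulative output scale and no bias-file weighting
  are provided.
* Presence-vs-background AUC depends on prevalence and background size and
  is not comparable across species or studies without care.
* Cross-validation is random k-fold; spatially structured partitions
  (block/checkerboard) are out of scope.
* The gap analysis is pure overlay accounting; it does not prioritize
  complementary areas.
* Raster I/O is plain-text ESRI ASCII grid; for very large real grids a
  binary raster backend would be the practical choice.
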