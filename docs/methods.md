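# Methods

## Scope and data model

`sdmrisk` implements a complete correlative species-distribution-modelling
(SDM) workflow for climate-change vulnerability assessment: occurrence
cleaning and spatial thinning, collinearity pruning of predictors,
species-specific calibration regions with background sampling, a
weighted-average ensemble of four presence-background algorithms evaluated
by spatial-block cross-validation, clamped projection onto multi-GCM
future predictor stacks, and classification of projected range change into
IUCN criterion A3(c) categories under unlimited-dispersal (UD) and
no-dispersal (ND) scenarios.

All rasters live on one shared geographic grid (default cell size 2.5
arc-min ≈ 4.6 km at the equator), stored as float arrays with NaN
no-data; a masked cell is masked in every layer. Grids must match
bit-exactly between current and future stacks — there is deliberately no
on-the-fly resampling, because silent resampling is a classic source of
corrupted SDM projections.

## Occurrence preparation

Records are restricted to a collection-year window (default 1960–2005),
validated for parseable coordinates inside [−180,180]×[−90,90], and
de-duplicated to at most one record per grid cell (first record in stable
input order wins; every removal is counted by reason). Spatial thinning
then seeks the *largest* subset of records in which every pairwise
great-circle distance (haversine, sphere radius 6371.0088 km) is at least
a minimum distance set by dispersal group: 5 km (small mammals), 10 km
(volant), 20 km (large). Exact maximization is the NP-hard maximum
independent set problem, so a randomized heuristic is used: repeatedly
delete a random member of the currently most-conflicted points until no
conflicts remain, repeat `n_tries` times (default 100) and keep the
largest survivor set. The distance constraint is asserted on the output,
never assumed. On random instances of ≤ 15 points the heuristic matches
an exhaustive subset-enumeration optimum in ≈ 99% of cases (measured by
`scripts/acceptance.py`).

## Predictor preparation

Collinearity is pruned by stepwise variance inflation factors:
VIF_j = 1/(1−R²_j) with R²_j from ordinary least squares of layer j on
the remaining layers, computed over a seeded random sample of unmasked
cells (default 10,000 — sampling makes the cost independent of grid
size). While any VIF exceeds the threshold (default 10) the single worst
layer is removed; exact ties break alphabetically for determinism, and a
perfectly collinear layer (R² numerically 1) has infinite VIF and is
removed first. Future predictor sets get their own VIF pass; if a layer
that survives on current data violates the threshold in a future set,
this is logged and flagged in the manifest, but the current-data survivor
set is what the models use.

Future stacks are assembled per GCM from the GCM's dynamic layers plus
the current static layers (e.g. vegetation continuous fields, assumed
constant into the future), with training bounds copied from the current
stack. Before projection every dynamic layer is *clamped* (clipped) into
the [min, max] observed over the calibration cells — constrained
extrapolation. Clamping is idempotent and refuses to run when bounds are
missing. ExDet novelty surfaces are provided to quantify what clamping
hides: NT1 ≤ 0 sums proportional univariate range extensions (NT1 < 0
iff some predictor leaves its training range), and NT2 is the Mahalanobis
distance to the reference mean, as a ratio of the maximum reference
Mahalanobis distance, defined only where NT1 = 0 (values > 1 flag novel
predictor *combinations*). ExDet is diagnostic by default; masking
predictions with it is opt-in.

## Calibration region and spatial cross-validation

The model-fitting domain is the minimum convex polygon (MCP) of the
occurrences, buffered by the mean over all unordered record pairs of
great-circle distance. Kilometre-true buffering is done in a local
azimuthal-equidistant projection centred on the occurrence centroid.
With fewer than three usable (or collinear) points the buffered hull
degenerates gracefully to buffer disks / a corridor. If the buffered MCP
covers more than 50% of the study area — measured as the fraction of
unmasked cell centres inside the polygon, recorded in the output — the
whole study area is used instead. Background points (default 10,000) are
drawn uniformly, without replacement, at unmasked cell centres inside the
region; if fewer cells exist, all are used with a warning.

Cross-validation blocks are the four quadrants at the occurrence median
longitude and latitude; points exactly on a median go to the lower-indexed
(west/south) block, and background points are split by the same rule so a
fold holds out an entire quadrant of both classes. Folds with a
single-class test or training set are skipped and logged.

## The ensemble

Member algorithms (all scikit-learn estimators emitting probabilities in
[0,1], with balanced class weights against the 100:10,000
presence:background imbalance):

| name | implementation | notes |
|---|---|---|
| maxent-like | standardize → quadratic features → L1 logistic (C=1) | sparse quadratic response surface |
| random-forest | 100 trees, min leaf 2 | |
| boosted-trees | histogram gradient boosting, depth 3, 100 iters | |
| linear-logistic | standardize → L2 logistic | the GLM baseline |

The subset of algorithms is chosen by occurrence count (all four at
n ≥ 30; the tree ensembles are dropped progressively below that; the hard
minimum is 5 presences), reflecting that data-hungry learners overfit
sparse species. Variable screening fits an initial equal-weight ensemble
on all candidates and measures each predictor's permutation importance —
the mean over 5 seeded shuffles of 1 − Pearson correlation between
original and shuffled-column consensus predictions, normalized to sum to
100% — retaining predictors above 5%, and never more predictors than
presences.

Member weights are CV TSS floored at zero and normalized (if every member
has TSS ≤ 0 the weights fall back to equal, with a warning). The
consensus is therefore a convex combination of member scores. Ensemble
CV AUC/TSS are fold means of the weighted consensus of held-out member
predictions. The binarization threshold is the max-TSS threshold (score ≥
threshold ⇒ suitable) of the pooled out-of-fold consensus predictions.
Future projections are computed per GCM on clamped stacks and aggregated
cell-wise by the median (even counts average the two central values);
per-GCM surfaces are retained for provenance.

## Change metrics and threat categories

Species richness is the cell-wise sum of per-species suitabilities
(expected species count); a binary-range variant gives integer counts.
Temporal turnover is the per-pixel Bray–Curtis dissimilarity
Σ|c_s−f_s| / Σ(c_s+f_s) between current and future composition (0 = no
change, 1 = complete replacement); pixels empty in both periods have no
defined composition and are reported as 0 but flagged. Range change uses
binarized ranges in cell counts; under ND the future range is intersected
with the current one, so ND loss ≥ UD loss and the ND category is never
less severe. The A3(c) mapping is strict at the boundaries: loss of
exactly 100% → EX, >80% → CR, >50% → EN, >30% → VU, otherwise LC; a
positive change is reported as Expanding. Time horizons (2050, 2070) are
treated as three generations each, as a fixed convention rather than a
modelled quantity.

## The virtual-species simulator

The simulator provides ground truth for every downstream stage.
Landscapes are stationary Gaussian random fields with an exponential
correlogram exp(−d/range), generated by circulant spectral embedding
(deterministic per seed), standardized per layer, and mixed through the
matrix square root of a user-supplied positive semi-definite correlation
matrix, so empirical inter-layer correlations converge to the target as
the grid grows. Virtual species have parametric niches — by default a
product of Gaussians over 1–3 active predictors, suitability
Π_j exp(−(x_j−μ_j)²/2σ_j²) ∈ [0,1] — and presences are drawn with
probability proportional to suitability × an optional sampling-bias
surface, jittered within the source cell, with optional verbatim
duplicates emulating multi-source compilations. Pseudo-futures apply
known additive/multiplicative shifts to dynamic layers; pseudo-GCMs add
independent zero-mean noise on top; static layers are copied
bit-identically.

What the simulator does *not* emulate: real climate variable semantics
and their strong mutual correlation structure (unless requested),
topography, dispersal dynamics, imperfect detection, and temporally
autocorrelated GCM disagreement. Passing the truth-recovery benchmark
therefore demonstrates that the pipeline's machinery is correct and
unbiased under its own assumptions, not that any real-data assessment is
accurate.

## The truth-recovery benchmark and its calibration

The benchmark (`sdmrisk.experiments`, also run by
`scripts/acceptance.py`) uses a 100×100-cell landscape with 6 independent
predictors (autocorrelation range 10 cells), 20 species whose niches sit
on the first 3 predictors with μ ~ U(−1,1) and σ ~ U(0.25,0.5) (in layer
standard deviations), 100 presences each (5% duplicates), 5-km thinning,
4 pseudo-GCMs (noise sd 0.15) and additive shifts of +0.8 sd (2050) and
+1.3 sd (2070). Species whose true range covers fewer than 100 cells or
more than 30% of the landscape are redrawn deterministically.

Two calibration choices deserve explanation:

- **Specialist niches.** Endemic, narrow-ranged species are the target of
  this kind of assessment. With broad niches (σ ≈ 1) the simulated
  species occupy ~30% of the landscape, and an oracle analysis — using
  the *true* suitability as the classifier on the same spatial folds —
  shows a discrimination ceiling near AUC 0.70: no model can look good on
  a landscape where presence and background environments barely differ.
  Specialist breadths put the oracle ceiling, and the fitted ensembles,
  in the realistic 0.9+ range.
- **The truth range is a potential-range floor, not a core-habitat
  cutoff.** The truth range is defined as suitability ≥ 0.05. The max-TSS
  threshold of any presence-background classifier sits analytically near
  the *mean landscape suitability* (maximizing sensitivity + specificity
  balances the presence and background score densities, which for
  sampling ∝ suitability happens at E[s]), i.e. at 0.02–0.1 for
  specialists — never near 0.5. A truth range defined at 0.5 would
  measure core habitat while the estimator measures potential range, and
  the two disagree by construction for *any* estimator, however good (we
  measured oracle Jaccard ≤ 0.25 across all breadths tried). With the
  commensurable floor, the benchmark measures estimation error only.

Measured at this scale (seed 1): ensemble spatial-CV AUC 0.91–0.95 and
TSS 0.77–0.87 for 20/20 species; UD range change within ±10 percentage
points of truth for 85% of the 40 species×horizon assessments; A3(c)
category agreement 75%; heuristic thinning optimal on 99/100 small
instances. Problem sizes were chosen so the whole benchmark runs in a few
minutes on one CPU.

## Known limitations

- **Clamping inflates projected expansions.** For species whose niche
  optimum lies near the upper edge of the training range, clamped future
  predictors saturate at the training maximum and the projected
  suitability stays high across large novel-climate areas; estimated
  expansions can then overshoot substantially (losses are much less
  affected). This is a faithful property of constrained extrapolation,
  visible in the benchmark's few >10-point misses, all of which are
  expanding or near-stable species. The ExDet surfaces exist precisely to
  flag where this occurs.
- The max-TSS threshold depends on the background sample and on the
  spatial folds; it is recorded in every output so users can substitute
  their own rule.
- Range change is counted in cells, not km²; at 2.5 arc-min over a
  continental extent the cell-area gradient is modest, and an equal-area
  weighting hook is the natural extension.
- The thinning heuristic is not an exact maximizer (the exact problem is
  NP-hard); its measured optimality gap on small instances is ~1%.
- Category agreement is intrinsically capped by classification-boundary
  effects: a species whose true loss is 49% and estimated loss 51% counts
  as a category mismatch however small the numeric error.
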