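# Methods

`morphoinvasion` implements a pipeline that asks whether the shape a breast
cancer cell adopts two hours after adhering to an extracellular-matrix (ECM)
coating predicts how strongly that same ECM cue drives 2D migration and 3D
spheroid invasion. The pipeline has five computational stages — morphometry,
motility metrics, condition-level aggregation, boosted-stump classification,
and partial least squares (PLS) regression — plus a synthetic-data generator
that stands in for the wet-lab assays and provides a known ground truth.

## Cell-shape morphometry

Input is an integer label image (0 = background) with a physical pixel size.
Cells touching any image border are discarded before measurement because
their outlines are truncated by the field of view. Regions below 9 px are
rejected as debris; holes are filled (cytoplasm masks are treated as simply
connected). Eleven parameters are computed per cell:

| parameter | definition | units |
|---|---|---|
| area | pixel count × pixel_size² | µm² |
| perimeter | length of the sub-pixel boundary polygon | µm |
| mean radius | mean distance of region pixels to the nearest background pixel | µm |
| min/max Feret | extremal widths between parallel tangents (rotating calipers) | µm |
| aspect ratio | major/minor axis of the moment-fitted ellipse (≥ 1) | — |
| eccentricity | of the moment-fitted ellipse; 0 = circle | — |
| compactness | 2π · (mean squared pixel distance from centroid) / area; 1 = disk | — |
| extent | area fraction of the axis-aligned bounding box | — |
| form factor | 4π·area/perimeter²; 1 = circle | — |
| solidity | area / convex-hull area; 1 = convex | — |

Numerical choices that matter:

* **Perimeter.** Pixel-edge counting overestimates a disk's perimeter by
  ~27% and marching squares on raw binary data by ~5.5%, which would push a
  circle's form factor to 0.79/0.90 instead of 1. We therefore contour the
  Gaussian-smoothed binary image (σ = 1 px) at the 0.5 level; a radius-200
  disk then scores form factor 0.99. Thin regions that vanish under
  smoothing fall back to the raw binary contour.
* **Compactness normalization.** The raw mean-squared-distance/area ratio
  equals 1/(2π) for a disk; the 2π factor anchors a filled disk at exactly 1
  (irregular shapes score above 1).
* **Solidity.** Defined as the standard convex-area ratio, so a circle
  scores 1, not 0.
* **Eccentricity floor.** Rasterization gives a small disk a genuinely
  nonzero eccentricity (≈ 0.1 at r = 30 px, falling roughly as r^-0.75);
  circle-anchor checks therefore use disks of r ≳ 100 px.
* **Feret diameters** come from exact rotating calipers over the convex
  hull of the boundary polygon (ties keep the first-encountered
  orientation); degenerate 1-px-wide regions get aspect ratio capped at 100
  and are flagged.
* Coordinates are 0-based with pixel centers at integer positions; the
  centroid is the unweighted pixel-center mean.

## Migration and invasion metrics

Trajectories are (t, x, y) tables at nominally 10-min spacing over 16 h
(97 samples). Speed is total path length over elapsed time (µm/min);
persistence is net start-to-end displacement over total path length, in
[0, 1]. Missing frames contribute one longer step; nothing is interpolated.
A track that never moves has undefined persistence (NaN, not 0), and tracks
under 3 points are excluded from population statistics because a 2-point
track has persistence 1 by construction. 3D invasion is quantified per
spheroid as the fold change in projected area, day 5 over day 1.

## Condition-level analyses

Per-condition summaries are the arithmetic means of the 11 shape features,
speed, persistence and fold change. The clustering analysis mean-centers the
condition × feature matrix per feature and agglomerates with distance
1 − Spearman ρ and average linkage; ranks make the distance scale-free, so
no additional standardization is applied to the heatmap values. Equal-height
merges are resolved toward the lexicographically smallest member label so
the dendrogram is deterministic; the implementation is validated against
SciPy's average-linkage on the same distances. The kNN graph (input to a
SPRING-style force-directed view) and PCA both operate on per-feature
z-scored single-cell features pooled across conditions; the 2D layout is a
deterministic visualization hook (seeded spring layout), not a quantitative
output. The force-directed layout engine itself is not re-implemented.

## Classification of low/high responses

Conditions are labeled from their mean response: speed strictly above
0.5 µm/min is "high"; invasion fold change strictly above 10 (mesenchymal
lines) or 8 (epithelial lines) is "high" — equality at the threshold is low.
Cells inherit their condition's label and classifiers are trained on
per-cell feature vectors, the only sample size large enough to train on.

The learner is discrete AdaBoost over decision stumps with the conventional
defaults (50 estimators, learning rate 1). Stump thresholds are midpoints
between consecutive sorted unique feature values; weighted-error ties break
toward the smaller threshold, then the lower feature index; initial weights
are uniform per cell. Training stops early at weighted error 0 (the perfect
stump is kept) or ≥ 0.5. Weighted errors are rounded at 1e-12 before
comparison so tie-breaking is immune to float-summation noise. AUROC is
computed in its Mann–Whitney pair-counting form with ties counted ½.

Generalization is scored by leave-one-condition-out folds: all cells of one
condition are held out per fold and the pooled held-out scores are scored
once. Because each training fold is class-imbalanced (a whole condition is
missing), the raw decision scores carry a per-fold offset that biases the
pooled AUROC — severely below 0.5 for pure-noise features. Each fold's
held-out scores are therefore centered on that fold's mean training score,
which removes the offset (null AUROC returns to ~0.5) while leaving genuine
between-class separation intact. Training-set AUROC is reported side by
side; note that a 50-round boosted model inflates training AUROC well above
0.5 even on pure noise, so the cross-validated column is the meaningful one.

## PLS regression

Rows are conditions (per-condition means), matching the design in which a
model trained on known ECM cues is asked about a new one. X (11 shape means,
or migration metrics) and Y (speed, persistence, invasion — jointly by
default, or per response) are autoscaled to zero mean and unit variance per
column. Components are extracted by NIPALS (tolerance 1e-10, ≤ 500
iterations, start vector = the scaled Y column of largest variance, hence
deterministic), deflating X and Y per component. Zero-variance predictors
are dropped with a warning; the component count is truncated to the
available rank.

Diagnostics:

* **R²** — cumulative fraction of scaled-Y variance captured at 1..A
  components.
* **Q²** — leave-one-condition-out: each fold refits the model, recomputing
  the scaling on the training rows; Q² = 1 − PRESS/TSS with TSS about the
  training-fold means, and errors accumulated on the scaled axis so
  responses with different units are comparable.
* **Permutation test** — Y rows are scrambled against X, Q² recomputed per
  permutation (default 1000; p-values use the add-one correction
  (b+1)/(N+1)).
* **VIP** — VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a), with
  SSY_a the Y variance explained by component a; the per-response variant
  weights SSY_a by that response's q loading. Σ VIP² = p in both variants,
  and VIP > 1 flags important predictors.
* **Component choice** — the smallest A within δ = 0.02 of the maximum Q²,
  refusing any A at which Q² has dropped by more than δ; all-negative Q²
  returns 1 with an overfitting warning.
* **Percent error** — 100·|pred − actual|/|actual| per response; an actual
  of 0 is reported as undefined rather than infinite.

Model augmentation extends the training matrix with rows from another cell
line, recomputes the scaling and refits at the same A — the "add the new
line's baseline condition" experiment. No cell-line indicator column is
added; rows are simply pooled.

## Synthetic data generator

The generator emulates the three assays with three independent shape knobs
per condition that map onto the three empirical feature families:
`size_scale` (mean equivalent-disk radius, µm → size features), `elongation`
(target mean eccentricity → elongation features) and `irregularity`
(boundary-noise amplitude → irregularity features).

* **Masks.** Cells are ellipses of the requested eccentricity (equivalent
  radius preserved) whose boundary radius is modulated by unit-RMS Fourier
  noise of orders 2–6 scaled by `irregularity`; cells are placed without
  overlap on a 1024×1024 canvas at 0.65 µm/px, with centers drawn over the
  whole canvas so some cells are clipped by the border (exercising border
  exclusion). Per-cell scatter: lognormal radius and clipped-normal
  eccentricity, both governed by `shape_sd`.
* **Trajectories.** Persistent random walks, 97 samples at 10 min: fixed
  step length `speed_base × 10 min` and wrapped-Gaussian turning angles.
  The turning σ is read from a calibration table (σ → expected net/total
  ratio of a 96-step walk, computed once by Monte Carlo at 2·10⁵ tracks per
  grid point and frozen in the source), so `persistence_base` equals the
  expected measured path ratio. Ratios below the uncorrelated-walk baseline
  (~0.09) are unreachable and clamp to the largest σ. Optional per-cell
  lognormal speed scatter (`speed_cv`) and Gaussian localization noise
  (`position`, µm).
* **Spheroids.** Day-1 areas are lognormal around 10⁵ µm²; the fold change
  is 1 + (F₀ − 1)·exp(β·z)·ε with condition latent z = (elongation − 0.5,
  irregularity − 0.15, log(size/20 µm)), coupling vector β
  (`invasion_link`), base fold F₀ and mean-one lognormal noise ε, floored
  at 1 (a spheroid never shrinks below its starting area). With β = 0 and
  noise off the fold equals F₀ exactly, and the mean fold is analytic,
  which the moment-recovery tests exploit.
* **Determinism.** One integer master seed; per-condition and per-cell
  streams are derived by SHA-256 hashing of (seed, condition, stream,
  index), so studies are bit-reproducible and conditions are independent.

Two canned designs set the study conditions:

* `default_study_specs` — five conditions mimicking no ECM / Collagen I /
  Fibronectin / Tenascin C / Collagen IV for a mesenchymal-like line:
  sizes 14–24 µm (areas ~0.6–1.9·10³ µm²), eccentricities 0.35–0.80, speeds
  0.25–0.65 µm/min, fold changes ~2–12 with β = (3.5, 4.0, 0) and F₀ = 4 so
  the collagens cross the fold-change-10 labeling threshold and the rest do
  not, matching the measured axis ranges and orderings.
* `recovery_study_specs` — eight conditions for parameter-recovery
  experiments: an elongation ramp 0.35–0.85, irregularity levels 0.04–0.32
  in a permutation kept weakly correlated with the ramp, and size levels
  14–28 µm shuffled to be near-orthogonal to both drivers so size features
  act as realistic nuisance variation rather than signal. Invasion couples
  only to elongation and irregularity (β = (1.2, 1.4, 0), F₀ = 4, fold
  noise σ = 0.15 over 18 replicates), keeping the latent exponent within
  ±0.6 where the exponential link is near-linear — a strong-link regime a
  condition-level linear model can be expected to recover. 50
  cells/condition keeps a full study under ~4 s.

What the generator does **not** emulate: nucleus/cytoplasm structure,
intensity or texture, cell contacts, division, segmentation errors,
drift or stage jitter in tracking, and any nonmonotone shape–invasion
relationship. Passing recovery tests therefore show that the analysis code
recovers a known coupling from realistic measurement noise — not that the
biological claim holds for real images.

## Problem sizes and tolerances in the test suite

Analytic anchors use r = 200 px (form factor, eccentricity, compactness,
extent) and r = 90 px (mean radius) disks. Oracle suites use 100 generated
perturbed-ellipse fixtures (< 1% agreement on area/extent/eccentricity
against direct pixel arithmetic). Recovery experiments use the 8-condition
study at 50 cells/condition: leave-one-condition-out invasion percent error
is averaged over three independent studies (the per-study mean is ~10% with
occasional extrapolation-dominated conditions above 25%), VIP recovery is
tallied over 50 independent studies, and the augmentation experiment
compares mean held-out error before and after adding the shifted line's
baseline row. Permutation tests in the suite use 100–200 permutations;
the library default is 1000.
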