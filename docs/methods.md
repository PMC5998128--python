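# Methods

## Pixel classification

Foreground/background separation is a one-parameter binary classifier on
intensity: a pixel belongs to the foreground class iff its intensity is
greater than or equal to a decision boundary θ.  θ is learned by
exhaustive maximisation of the between-class variance of the intensity
histogram (Otsu's criterion).  This is assumption-free about the class
densities, which matters because fluorescence backgrounds are not
Gaussian after clipping and gradient effects.

Numerical choices:

* The search runs over native gray levels for 8-bit data.  12- and
  16-bit data are binned to 256 equal-width bins for the search and θ is
  mapped back to the native scale (θ = bin index × bin width); this
  avoids sparse-histogram instability, at the cost of quantising θ to
  the bin width (16 levels for 12-bit data).
* Ties in the objective are broken toward the lowest θ, making the
  learner fully deterministic.  The test suite verifies equality with a
  brute-force exhaustive search on 100 random images, and agreement with
  `skimage.filters.threshold_otsu` up to the inclusivity convention
  (our foreground is ≥ θ; skimage's is > t, so θ = t + 1).
* A constant training region raises a degenerate-input error: no
  foreground/background split exists.
* The training region defaults to the whole image and can be restricted
  to a rectangle when an acquisition contains a representative subregion.

Known limitation — sparse images.  The between-class variance of a
two-mode histogram with foreground weight w_f ≈ w_f·Δµ², while splitting
the background noise mode alone scores ≈ 0.64·σ_bg².  With bright cells
(Δµ ≈ 150 of 255) on a background of SD ≈ 6, the cell/background split
wins only when foreground coverage exceeds roughly 0.1 % of pixels.
Below that (near-empty fields, extreme dilutions) per-image learning
collapses to splitting the noise.  The pipeline therefore offers a
global-θ mode that learns θ once on a populated reference frame and
applies it to the whole batch; the dilution-series experiment uses it.
Real deployments at trace densities should do the same or use a larger
training region containing cells.

## Connected components and morphology

Components are maximal connected foreground regions, 8-connectivity by
default (4 is configurable); 8 avoids splitting filaments at diagonal
joints.  Regions below `min_component_area_px` (default 4 px) are
removed as shot noise and their pixel count logged.  Labels are
renumbered in raster-scan order of each region's first pixel so output
is deterministic.

Seven features per component:

| feature      | definition                                     | notes |
|--------------|------------------------------------------------|-------|
| area         | pixel count (µm² via calibration²)             | |
| perimeter    | boundary contour length, diagonals weighted √2 | raw border-pixel counts would inflate c |
| eccentricity | focal distance / major axis of the moment-fitted ellipse | 0 = circle, 1 = line |
| compactness  | c = 4πA/P²                                     | 1 for an ideal circle |
| convex area  | hull area of pixel-corner points               | ≥ pixel count by construction |
| solidity     | area / convex area                             | ≤ 1 by construction |
| extent       | area / bounding-box area                       | ≤ 1 |

Compactness is theoretically ≤ 1 but discretized perimeter estimates
push it above 1 for small round objects (a ~60 px disc measures
c ≈ 1.0–1.2).  Values are reported unclipped with a warning: clipping
would destroy the ranking information the classifiers use, and the
unclipped value remains comparable across objects measured by the same
estimator.  The convex hull treats each pixel as a unit square and hulls
the corner points; this keeps solidity ≤ 1 exactly, at the cost of a
hull ≈ P/2 larger than a pixelized hull (a rasterized disc's solidity is
therefore ≈ 0.95, not 1.0).  Degenerate single-pixel components (which
the area filter normally removes) are defined to have ε = 0, perimeter
1, and hence c capped at 4π, with a warning.

Scale and rotation behaviour is property-tested: doubling resolution
multiplies areas by 4 and leaves the dimensionless features within 5 %
(discretization bias is strongest for rasters under ~500 px, so the
test anchors at a larger base); ε and c vary by ≤ 0.05 under rotation.

## Classification

Two-species mode is the threshold cascade given in the README, with the
boundary inclusivities exactly as stated: the filamentous branch uses
≥/≤, the unicellular branch strict </>, so the two branches are
provably disjoint.  Defaults ω = 0.70 and τ = 0.80 are midpoints between
representative feature values of the two cyanobacteria (filamentous
ε ≈ 0.85, c ≈ 0.64; round ε ≈ 0.52, c ≈ 0.98).  The area windows ψ are
derived from Phase-1 calibration: [0.25×, 4×] the unit-cell area for the
unicellular class, and [0.25×, 64×] for the filamentous class — the
upper filamentous bound spans many unit cells because one connected
component is a whole filament; 64 cells comfortably covers filaments
that survive 2-minute sonication.  Areas are compared in px²; µm²
entries are converted through the calibration.

Three-species mode adds the spindle-shaped alga, which the cascade
cannot separate from short filaments.  It uses an SVM with the full
(inhomogeneous) quadratic polynomial kernel (γ⟨x, y⟩ + 1)², C = 1,
one-vs-one multi-class reduction, and per-column z-scoring fitted on the
training folds only.  Evaluation is stratified five-fold
cross-validation, pooled into a single confusion matrix; every instance
is predicted exactly once.  All fold shuffling is seeded.

Evaluation metrics are the standard one-vs-rest reductions:
specificity TN/(TN+FP), sensitivity ≡ recall TP/(TP+FN), precision
TP/(TP+FP), accuracy (TP+TN)/total, F1 the harmonic mean of precision
and recall.  (Some sources misprint sensitivity with a TN numerator;
the recall-consistent definition is used here.)  Zero-denominator
ratios are reported as NaN with a warning — never silently as 0 — and a
macro-average across classes is offered for multi-class summaries.

## Enumeration

* Phase 1: the unit-cell projected area is the mean ± SD of component
  areas over single-cell images (sonicated, size-filtered suspensions);
  a warning fires below 10 cells.
* Phase 2: unicellular classes are counted as objects; the filamentous
  estimate is Σ area / unit area, reported as a real (fractional cells
  are meaningful for area division; rounding is display-only).  Its SD
  propagates the calibration uncertainty by the delta method:
  sd = estimate × (σ_u/u) / √n_cal.
* Concentration: cells/ml = (cells per field) / (grid area × depth in
  ml) × dilution factor.  Chamber depth defaults to 100 µm and grid area
  to 1 mm² (a standard hemocytometer: 0.1 µL per field); both are
  config-driven and must be matched to the user's optics — in particular
  `grid_area_um2` should be the imaged field area when a camera frame
  does not cover a full grid square.
* Mixture proportions normalise per-class estimated cells to sum to 1,
  excluding the "neither" class; an all-zero batch yields NaN with a
  warning rather than an arbitrary split.
* Overlapping cells are not resolved beyond connectivity: aggregates
  count as one object (sample preparation by sonication is assumed to
  break them).  This is a known bias at high densities.

## Synthetic scene generator

The generator emulates fluorescence-contrast acquisitions of the three
morphotypes:

* round unicells as discs with projected areas ~ N(24.6, 3.4²) µm²
  (typical *Microcystis*-sized cells);
* filaments as chains of abutting ellipses, one per cell
  (cell ≈ 6.5 × 5.25 µm, unit area ≈ 26.8 µm²), 8 ± 3 cells per
  filament with mild random curvature; centre spacing is 0.97 of the
  cell length so chains stay 8-connected, and the true per-filament cell
  count is recorded.  A filament is defined as ≥ 2 cells — a single-cell
  chain is morphologically a unicell — except in the Phase-1 calibration
  condition, which renders isolated single cells;
* spindles as thin ellipses (30 ± 8 µm × 2.5 µm);
* optional debris (irregular star-convex polygons of intermediate
  brightness) and a linear illumination ramp, emulating an untreated
  surface-water matrix.

Intensities are per-pixel Gaussian — cells 180 ± 12, background 30 ± 6
on the 8-bit scale, scaled for deeper bit depths and clipped — with no
point-spread function, partial-volume edges, Poisson shot noise, or
out-of-focus blur.  Spatial calibration defaults to 0.645 µm/px (a
6.45 µm sensor pitch behind a 10× objective, typical of scientific
CCDs).  Placement is rejection sampling with a 2 px separation margin,
so ground truth is exact and objects never merge; a spec too dense to
satisfy raises an error naming the class.  Identical seeds give
bit-identical scenes (integer-seeded PCG64, no time-based state).

What passing tests therefore show: the pipeline's logic — threshold
learning, component analysis, feature extraction, classification rules,
area calibration and unit conversion — is correct on images whose
difficulty comes from noise, debris, illumination gradients and shape
variability.  What they do not show: robustness to defocus, halo/PSF
effects, touching or overlapping cells, autofluorescent colonies, or the
full morphological diversity of natural assemblages.  Real-matrix
performance must be validated against manual counts.

The Gaussian feature-table generator draws the seven features
independently per class from configurable mean/SD pairs (defaults are
representative per-cell statistics of the three species, 272 cells per
class), truncated to each feature's valid range by resampling.  It
benchmarks the classifiers without rendering; independence across
features is a simplification — real features are correlated (area with
perimeter, etc.) — which makes the benchmark slightly easier than
measured feature sets.

## Validation experiments (`cyanocount.experiments`)

Problem sizes are chosen so cells cover ~0.5–5 % of each field (an
adequately populated counting field, and the regime where per-image
threshold learning is well-posed) and so the full suite runs in a few
minutes on one core: 480×640 to 600×800 px fields for enumeration
experiments, 300×400 px for single-cell calibration scenes, five images
per dilution level, 272 cells per class for the SVM benchmark.

* Count recovery: disc-only scenes (10–200 cells) are recovered exactly;
  fixed-size filament scenes (8 × 12 cells) are recovered within 10 % by
  area division against a calibration measured from rendered single
  cells.
* Dilution linearity: five levels spanning 500×, Poisson-drawn counts,
  global θ; recovered vs true counts regress with slope ≈ 1, R² ≥ 0.98.
* Mixture proportions: two-species mixtures at 100/80/60/40/20/0 %
  filamentous cells are recovered within 5 percentage points.
* Classifier sanity: the cascade separates rendered discs from filaments
  with zero cross-class errors at default thresholds; the quadratic SVM
  scores ≥ 95 % five-fold CV on the Gaussian benchmark and ~1/3 under
  label permutation.
* Calibration recovery: the mean of a N(24.6, 3.4²) µm² single-cell
  population (n = 100) is recovered within two standard errors.
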