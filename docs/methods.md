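# Methods

## Measurement model

A radiograph is represented by five labelled simple polygons (C3–C7) in
pixel coordinates, x rightward and y downward. All landmarks derive from
per-vertebra contours; the four alignment parameters derive from the
landmarks. Conventions that the data themselves do not fix are exposed in
`MeasurementConfig`:

* **anterior_side** (`right` default). Lateral radiographs do not encode
  laterality, so which image side is anterior is configuration. It fixes
  the SVA sign (+ = anterior displacement of C3), the lordosis sign
  (+ = lordotic, endplate lines diverging anteriorly) and which horizontal
  band of C7 is posterior.
* **band_fraction** (0.25 default, valid range (0, 0.5]). Endplate and
  corner detection restricts the contour to its leftmost or rightmost
  x-band of this relative width before taking the extreme-y point; the
  band suppresses outlier contour points far from the endplate. Ties in y
  resolve to smaller x, then earlier contour index, for determinism.
* **contour_source**. `polygon_direct` (default) uses the annotation
  vertices as the contour — exact for polygonal annotations.
  `raster` reproduces the mask pipeline: polygon → binary mask (a pixel is
  foreground iff its centre lies inside or on the polygon, even-odd rule)
  → Moore-neighbour boundary trace (8-connectivity, started at the
  top-most left-most foreground cell). Raster contours approximate the
  polygon to about one pixel, so raster-mode parameters carry an error of
  order 1 px / 1° at ≥1000 px image scale.
* **pixel_spacing** (1.0). Lengths are pixels unless a physical spacing is
  supplied; cohort tables generated here treat "length units" as generic.

Each endplate line joins the band-extreme points of *both* bands of its
contour (lowest pair for the C3 inferior endplate, highest pair for the C7
superior endplate): one extreme point per side is the minimal completion
of a band rule into a tangent line. The Cobb angle is the signed angle in
(−90°, 90°] between the two lines. Centroids always use the shoelace
polygon-centroid formula regardless of contour source, since the polygon
is the primary datum.

### Known limitation of the band rule

For a *kyphotic* C7 (superior endplate rising anteriorly), the highest
point of the posterior band of a dense (raster) contour is not the
posterosuperior corner but the point where the endplate crosses the band
boundary; detected SVA then shifts by up to the band width. This is a
property of the rule, not of its implementation — a sparse polygon contour
is unaffected because only the corner vertex lies in the band. Raster and
polygon-direct measurements therefore agree to tolerance only over
lordotic alignments (the range the three phenotypes occupy); kyphotic
raster SVA should be interpreted with this caveat.

## Synthetic data

### Parameter cohorts

`table1_config()` carries the published three-cluster profile: sizes
703/387/228 and per-cluster mean ± SD for all four parameters (total
n = 1318). `simulate_cohort` draws each parameter independently within a
cluster from Normal(mean, SD²) — no within-cluster correlations are
published, so independence is the minimal assumption — and shuffles rows
with a recorded permutation. Consequences worth keeping in mind:

* Real alignment parameters are correlated (curved and vertical length
  strongly so); simulated clusters are axis-aligned ellipsoids. Clustering
  and ANOVA results on simulated cohorts therefore emulate the *structure*
  of the clinical cohort, not its exact statistics, and dataset-dependent
  values (silhouette curves, a Calinski–Harabasz of ~1172 at k = 3) are
  not reproduction targets.
* Independent draws can produce vertical > curved, which no real spine
  (and no phantom) can realise — harmless for cohort statistics, but
  phantom generation redraws such tuples (see below).
* On the simulated cohort the three generating clusters overlap; k-means
  at k = 3 recovers them with adjusted Rand ≈ 0.7 (a smoke bound of 0.5 is
  asserted), silhouette favours k = 2 and the elbow rule k = 4 — the same
  ambiguity that required visual inspection of PCA plots in the clinical
  analysis. Model-selection correctness is therefore asserted on
  well-separated synthetic clusters instead.

### Spine phantoms

`generate_spine_annotation` builds five rectangular bodies (default
60 × 40 px) whose tilts run from −L/2 (C3) to +L/2 (C7) in steps of L/4,
so the C3 inferior and C7 superior endplate lines subtend exactly the
configured Cobb angle L. Centroids are chained by four steps:

* **default mode** — step directions follow the mean of adjacent tilts
  (an arc-like chain with spacing `segment_gap`), then all step
  x-components are sheared equally so the configured SVA holds exactly;
  vertical and curved length are reported in closed form from the chain.
* **explicit-length mode** — when `vertical_length` and `curved_length`
  are both configured, the chain uses two unit directions (two steps
  each), solved in closed form so that total path length, net vertical
  drop and net horizontal travel meet curved, vertical and SVA
  simultaneously. Infeasible combinations (a chain of length
  √(Δx² + vertical²) exceeding curved) raise rather than approximating.

Rectangles are used instead of anatomical silhouettes deliberately: the
endplate anchors and the posterosuperior corner are then exact polygon
vertices, which is what makes the ground truth closed-form and the
generator usable as a measurement oracle. The generator refuses
configurations whose tilt would push a corner out of the 25% detection
band (steep tilt on a tall narrow body). Optional uniform vertex jitter
(`jitter_px`, default 0) degrades the phantoms for robustness testing and
intentionally breaks exactness. Imaging noise, occlusion, osteophytes and
annotation-error models are out of scope.

## Statistics

* Z-scoring and all reported SDs use the sample convention (ddof = 1).
* `anova_oneway_from_summary` uses SSB = Σnᵢ(mᵢ − m̄)², SSW = Σ(nᵢ−1)sᵢ²
  — algebraically identical to the raw decomposition, which lets published
  summary tables be audited. From the printed summaries this reproduces
  the published F statistics for SVA (82.4), vertical length (825.0) and
  curved length (977.9) within 0.5%; the lordosis row reconstructs to
  ≈767 against a printed 755.5 (≈1.5%), a gap attributable to rounding of
  the printed means/SDs (and possibly to the unexplained difference
  between the 1371 analysed patients and the 1318 summed cluster sizes),
  so it is documented rather than asserted.
* Post hoc tests default to **Welch** pairwise t (per-group variances,
  Welch–Satterthwaite df) with Bonferroni ×3, because that choice — and
  not the pooled-variance alternative — reproduces the published pairwise
  p = 0.079 (vertical, clusters 1 vs 2) and p = 0.135 (curved, 1 vs 2);
  pooled (MSW-based, df = n − k) remains selectable. Groups with zero
  within-variance yield F = 0 (equal means) or a flagged infinity.
* The display writer renders p < 0.01 as "<0.01", mirroring the usual
  table convention; full-precision values are emitted as JSON.

## Clustering

Clustering defaults to the standardized four-parameter matrix;
`pca_scores` is selectable for the PCA-input reading. k-means uses
k-means++ seeding, best of 10 initialisations, Lloyd iterations to a 1e-6
shift tolerance (scikit-learn backend), deterministic for a given seed.
`scan_k` (default k = 2…8) additionally runs a warm-started replicate per
k (previous centroids plus the farthest point), keeping whichever solution
has lower WCSS — this guarantees a monotone non-increasing WCSS curve for
the elbow rule. `select_k` offers silhouette-max, an elbow formalised as
maximum perpendicular distance to the chord of the WCSS curve (ties →
smallest k), and manual choice. Davies–Bouldin is computed in-module so
that coincident centroids are flagged explicitly (infinite index with a
warning); singleton clusters take silhouette 0.

Phenotype naming is statistic-driven, not index-driven: the cluster with
the highest mean lordosis is *normal*; of the remainder, the one with the
longest mean vertical length is *long-neck*; the last is *forward-head*.
For k ≠ 3 neutral `cluster_i` names are used.

## Problem sizes and determinism

Simulated cohorts default to the published 1318 rows; phantom-based
geometry tests use grids over the published cluster-mean values and a few
dozen random configurations, with raster-mode checks at ≥1000 px scale.
Every stochastic routine takes an explicit seed (numpy `default_rng` /
scikit-learn `random_state`), and the CLI funnels one config seed through
all stages, so full runs are bit-reproducible.
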