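# Methods

This note documents the models, parameter choices and numerical
conventions behind `cucurbita`, and what the synthetic validation does
and does not demonstrate about real UAV imagery.

## The detection model

The pipeline assumes an orthorectified, uniform-GSD RGB raster in which
fruits are the only saliently orange-red objects. Pixel classification
uses only the raw R, G, B values as features — no texture, no indices —
because at ~1 cm GSD color alone separates ripe Hokkaido fruits from
canopy and soil. The random forest uses the conventional defaults
(bootstrap per tree, √3 ≈ 1–2 features per split, Gini impurity) with
500 trees; accuracy is flat well below that number, so the tree count
is not a sensitive parameter. A hook for extra per-pixel features
exists in `LabeledPixelSet` but is off by default.

Training pixels are sampled from the scene's truth labeling rather than
hand-digitized polygons: the fruit class is drawn from *visible* fruit
pixels (an analyst would not label pixels hidden under a leaf), the
background class from non-fruit pixels. The sample is split 50/50 into
train/test, and the reported confusion matrix uses a fixed evaluation
subset of 1000 pixels per class drawn from the test half, which
decouples the precision of the reported OA/PA/UA from the sample size.

## Morphology

Opening-then-closing with a 3×3 square kernel, zero-padded at the
borders. The order matters: opening first removes 1-px noise *before*
closing could solidify it. On convex blobs larger than the kernel the
sequence is idempotent, which the tests exploit.

## Ellipse reconstruction and splitting

Object boundaries are traced with marching squares at the 0.5 level on
a zero-padded crop (sub-pixel, closed contours); the ellipse is a
direct least-squares conic fit to those boundary points. Rendered
fixtures show the fitted full axes are within ~1 px of truth across
orientations, with no systematic bias. Objects with fewer than 5 pixels
cannot constrain an ellipse and raise a degenerate-object error.

Two diagnostics flag merged multi-fruit blobs:

* **aspect ratio** = major/minor of the fitted ellipse, threshold 2.2;
* **difference score** = |ellipse Δ object| / |ellipse| on the pixel
  grid, threshold 0.15,

combined with OR. The thresholds were calibrated on rendered fixtures,
not on field data: tangent fruit pairs measure difference ≥ ~0.17
(equal tangent circles ≈ 0.25) while clean single fruits stay below
~0.05, so 0.15 separates pairs with a wide margin; the aspect condition
exists for configurations an ellipse can still fit snugly — collinear
chains and end-to-end merges — and its threshold of 2.2 keeps the
false-split rate on legitimately elongated single fruits (elongated
plan outlines occur because diameter and height are distinct physical
dimensions) near 1%. A tangent pair of equal circles has aspect ≈ 2.0,
below the aspect threshold, and is caught by the difference condition.

Splitting places the *minimum-area rotated* bounding box (axis-aligned
boxes would make "parallel to the shorter side" meaningless for
obliquely merged pairs), divides it into three equal slabs parallel to
the short side, and removes the single 1-px cross-section of the
central slab with the fewest object pixels, ties broken toward the slab
center. Cut pixels belong to neither part, so the pixel union can only
shrink — this, plus a per-object iteration cap (10), guarantees
termination. Parts are re-labeled into 8-connected components and
fragments below the minimum object area (15 px ≈ 15 cm² at 1 cm GSD,
half the area of the smallest surveyed fruit) are discarded.

## Quantification

The oblate-spheroid volume V = (4π/3)(d/2)²(h/2) takes the longer
ellipse axis as diameter and the shorter as height. When a measured
fruit is taller than wide (vertical growers), the function warns: the
top view cannot observe the true height, and this is an intrinsic
limitation of the 2-D method, not a defect of the regression.

The weight regression includes an intercept by default (a
through-origin flag exists); physically the intercept should be near
zero and the slope near the flesh density. Predictions are floored at
0 g so tiny segmentation fragments cannot go negative. Retail classes
use half-open lower-inclusive bins ([500, 800) g etc.); class
percentages are rounded half-even to one decimal, and the marketable
share is 100·(total − count(<0.5 kg))/total.

## Yield grid

Cells (default 3 m) are anchored at the lower corner of the field
boundary's bounding box, edges lower-inclusive with the upper boundary
edge folded into the last cell, so binning is deterministic and grid
refinement is exactly conservative (2×2 blocks of the 1.5 m grid
reproduce the 3 m grid). Records outside the boundary are reported,
never silently dropped. Per-cell SDs are scaled to per-m² units;
the count-weight Pearson correlation uses non-empty cells.

## Evaluation

Matching is greedy nearest-first one-to-one within 0.5 m. The radius is
a design choice (the pairing tolerance between GPS-surveyed and
image-derived positions is not a measurable property of the synthetic
scenes); 0.5 m is ~3–4 fruit diameters yet below typical nearest-
neighbor spacing at ~1.4 fruits/m², and on separated instances greedy
matching provably coincides with the optimal assignment (tested against
brute-force enumeration). The precision audit replaces a human check:
a sampled detection is a true positive when its center pixel lies on
the truth footprint.

## The synthetic scene generator

The generator *is* the study condition, not a tuning knob. It renders:

* mottled soil/canopy background (smoothed thresholded noise field);
* fruits as filled rotated ellipses of d × h px at 1 cm GSD, orange-red
  with ±10% per-fruit channel jitter and per-pixel noise;
* an illuminated right half — fruit colors pushed toward light red,
  plus a near-white overexposure disc on each fruit — and a shaded left
  half with all channels multiplied by 0.6;
* leaf-green irregular polygons overpainting part of each occluded
  fruit (RGB only; the truth mask keeps the full extent and the
  per-fruit visible fraction is recorded, so occlusion effects can be
  stratified in evaluation);
* tangent pairs: the second fruit is placed along a random direction
  and nudged until the two rasters are 8-adjacent; all other fruits
  keep ≥ 5 px boundary spacing, by rejection sampling with a 100·n
  retry budget.

Fruit diameters and heights follow truncated normals
(13.8 ± 3.0 cm in [6, 21]; 12.4 ± 2.6 cm in [6.5, 19]) coupled by a
Gaussian copula with correlation 0.85. The copula preserves both
marginals exactly while expressing fruit-size allometry; with fully
independent draws about a fifth of fruits would be markedly taller than
wide, which mis-states the geometry a top-view method can face and is
not what correlated real fruit dimensions look like. Independence
remains available (`correlation=0`). Ground-truth weights are linear in
spheroid volume (slope 0.96 g/cm³, zero intercept — making the
mean-size fruit weigh ~1187 g — plus 35 g Gaussian noise, ~3% of that
mean).

What passing on these scenes shows: the geometry chain (classification
→ morphology → ellipse → splitting → spheroid → regression → grid) is
correct and robust to the modeled nuisances (illumination split,
overexposure, moderate occlusion, tangent pairs). What it does not
show: robustness to photogrammetric mosaicking artifacts, motion blur,
continuous shadows, color variation of real cultivars, or fruits fully
hidden under canopy — none of which the renderer attempts.

## Problem sizes and determinism

Default validation scenes are 900–1200 px squared (≈ 80–145 m²) with
60–200 fruits at field-realistic densities of 1–2 fruits/m²; full-image
classification is accelerated by predicting once per unique RGB triple.
All sampling, forest construction, weight noise and audits derive from
explicit integer seeds (per-stage streams spawned from one master
seed); rendering and all tabular outputs are bit-reproducible for a
fixed configuration.

## Known limitations

* Heights of vertically growing fruits are unobservable from nadir
  imagery; the spheroid model then substitutes the plan-view minor axis.
* The splitter assumes merged groups are chains of at most a few
  fruits; dense clusters with large mutual overlap are out of scope, as
  is instance segmentation of fruits fully covered by leaves.
* A long thin bridge between two blobs (rare after 3×3 opening) can
  leave elongated remnant fragments that are counted if they exceed the
  minimum area.
* GeoTIFF georeferencing is simplified to a world-file affine at
  uniform GSD in a local coordinate frame; full CRS handling is not
  implemented.
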