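# Methods

This note documents the models and procedures implemented in
`shellmetrics`, the assumptions behind them, and the choices made where the
design was genuinely open.

## Problem setting

A single Chinese softshell turtle (*Pelodiscus sinensis*) is photographed
from above on a uniformly colored board, together with a reference object
of known physical length. The task is to (1) separate the animal from the
background, (2) recover its position and orientation, (3) rotate it into a
canonical pose, (4) convert pixel extents of its shell into millimetres,
and (5) predict its body mass from those measurements with a linear
allometric model, so that animals can be sorted by weight without handling
each one on a scale.

## Segmentation: constrained linear color model

Each pixel is scored with a linear combination of its channels,
`I = Cr·R + Cg·G + Cb·B`, subject to `Cr + Cg + Cb = 0` and
`|Cr| + |Cg| + |Cb| > 1`. The zero-sum constraint makes the response
invariant under a uniform brightness shift of all three channels (until
values clip at 0 or 255), so the model keys on chroma, not illumination.
Pixels with `I ≤ Thresh` are foreground. The defaults `(-1, -1, 2)` with
`Thresh = 70` target a blue board: saturated blue scores ~+300 and is
rejected; the olive-gray animal scores below zero and is kept. The
response is computed in floating point from widened integers — with
coefficient magnitudes ≤ 3 the range is within ±765, so uint8 wraparound is
the only real hazard and is avoided by the cast.

A binary closing (dilation then erosion, square structuring element,
default 5×5, configurable) removes speckle holes from sensor noise. The
mask is padded with background before closing so the operation remains
extensive (never deletes foreground) at the frame border; the acquisition
geometry keeps the animal interior to the frame. The kernel size is a
package default, chosen to fill isolated noise pixels at VGA-to-1.3 MP
resolutions without bridging the gap between limbs; it is not derived from
any measurement protocol. Note that closing is extensive on concave
silhouettes: it slightly rounds the notches where head and tail meet the
shell, which is why even a noiseless phantom segments with F1 ≈ 0.9998
rather than exactly 1 after closing (thresholding alone is exact).

## Contour extraction: border following with hierarchy

Connected-component topology is recovered with the classic raster-scan
border-following algorithm (Suzuki–Abe). Foreground is 8-connected,
background and holes 4-connected — the standard pairing that keeps outline
and hole topology consistent. Each newly met boundary gets an integer
identifier (NBD) in discovery order starting at 2; 1 is reserved for the
frame. During a trace, a boundary pixel whose east neighbor is background
is marked `-NBD` in a working copy (the caller's mask is untouched), which
is what lets later scan rows distinguish already-traced boundaries and
recover each boundary's parent. The published start condition for hole
boundaries contains a misprint (`f ≥ 0`, which would match everything);
the implementation uses the original `f ≥ 1`.

`fill_contours` inverts the extraction. Outer boundaries contribute their
enclosed region (computed by flood-filling the 4-connected exterior of the
boundary within a padded bounding box). Hole boundaries subtract exactly
the 4-connected background component seeded at the east neighbor of the
hole's starting pixel. The seed-based rule matters: a foreground pixel can
be completely 4-surrounded by pixels of a zigzagging hole boundary while
being connected to the component only diagonally; "everything the exterior
flood cannot reach" would wrongly delete it, while the seeded flood
recovers the hole exactly. With this rule `fill ∘ extract` is the identity
on arbitrary binary masks, which the tests verify on hundreds of random
grids against a flood-fill labeling oracle.

## Pose: moments, orientation, heading

Raw moments `M00, M10, M01, M20, M02, M11` are exact integer-weighted sums
over the mask (foreground weight 1). Centroid: `xc = M10/M00`,
`yc = M01/M00`. With normalized central second moments
`a = M20/M00 − xc²`, `b = M11/M00 − xc·yc`, `c = M02/M00 − yc²`, the body
axis angle is `θ = ½·atan2(2b, a−c)`, which resolves the quadrant
ambiguity a bare arctangent leaves near `a = c`. One coordinate convention
is used everywhere: x = column, y = row, angles counterclockwise from +x
in a y-up sense (so `b` is negated in index space). Shapes that are
isotropic to within a relative tolerance of 1e-9 return θ = 0 by
convention. Moments can alternatively be computed from traced contour
points only (`estimate_pose(source="contour")`); the filled mask is the
default because it is less sensitive to boundary raster noise.

θ is an axis, defined modulo 180°. The directed heading in [0, 360) —
0 meaning the canonical pose, head pointing left — is resolved by the sign
of the third central moment of the foreground projected on the body axis:
the head protrudes beyond the shell rim and skews the projection
distribution toward itself. On a perfectly symmetric mask the skew
vanishes; the heading falls back to θ and a low-confidence flag is set. A
detector-based rule (finding the tail or abdomen explicitly) would be more
robust on real animals with splayed limbs; the skewness rule is exact on
the phantom geometry and is the package's default in the absence of a
detector.

Standardization rotates image and mask about the centroid by −heading so
the axis is horizontal and the head is at lower column indices, on a
canvas enlarged to hold the rotated frame. The image is resampled
bilinearly, the mask nearest-neighbor (keeping it binary); the affine map
actually applied is returned so downstream code can transform annotation
points. Foreground pixel count is conserved to well under 2% by
nearest-neighbor resampling; re-estimated orientation after
standardization lands within 0.05° of horizontal on phantoms (tests allow
0.5°).

## Morphometry

The scale factor is `s = Lb / Lbp` (mm/pixel) from a reference object of
real length `Lb` spanning `Lbp` pixels; lengths convert linearly,
`L = s·Lp`. A single isotropic factor assumes the camera plane is parallel
to the board. Extents of a standardized mask are bounding-box pixel counts:
length along columns (the body axis), width along rows. Using box extents
(rather than perpendicular caliper width at the widest contour point)
matches measuring from axis-aligned detection boxes; on convex-ish shells
the two coincide.

The five shell parameters are carapace length/width (LC, WC; dorsal view),
plastron length/width (LP, WP; ventral view) and plastron full length (LF,
plastron front edge to tail base; ventral view). LP/WP cannot be told
apart from the whole ventral silhouette without locating the plastron, so
`measure_record` accepts labelled part regions — masks or axis-aligned
boxes — from any source (a trained part detector in production; the
generator's exact body mask in tests). The whole-silhouette pipeline
(`run_measure`) fills the fields its single view can support and flags the
rest missing.

## Mass model

Mass (g) is fitted on a predictor subset of the five lengths (mm) by
ordinary least squares with intercept; the canonical subsets compared are
{LC, WC}, {LP, WP} and {LP, WP, LF}. The solver is numpy's least squares
preceded by an explicit QR rank check that names the collinear column(s)
instead of silently regularizing. Evaluation reports R², MAE, MSE, RMSE
and MaxRE = max over samples of |ŷ−y|/y in percent — the worst-case
relative grading error for a mass-based sorter. Evaluation is in-sample by
default, matching how such feasibility models are usually quoted; nothing
prevents evaluating a model on held-out records. Published feasibility
numbers for this species (R² ≈ 0.92, RMSE ≈ 40 g at n = 153) depend on an
unavailable measured dataset; the synthetic population below is calibrated
so the same metric suite lands in the same regime, which checks the
machinery, not the biology.

## Detector components

Four primitives used by attention-augmented single-stage detectors are
provided as pure numpy functions (no autodiff; training is out of scope):

- **SimAM** assigns each neuron `t` in a channel of `M = H·W` activations
  the closed-form minimum of a linear-separability energy,
  `e*_t = 4(σ̂²+λ)/((t−μ̂)² + 2σ̂² + 2λ)`, and reweights the map by
  `sigmoid(1/e*)`. `μ̂` and `σ̂²` are the mean and variance of the *other*
  `M−1` activations (leave-one-out, computed in O(1) per neuron from the
  channel sum and sum of squares). With these statistics the closed form
  equals the numerically minimized energy to machine precision, which is
  how the tests verify it; the common fast approximation that reuses
  whole-map statistics differs at third order and would not satisfy an
  exact oracle. Default λ = 1e-4.
- **SE** gates channels by `sigmoid(expand(relu(reduce(GAP(x)))))`. The
  rectifier between the two linear maps is part of the standard design and
  is required for the bottleneck to be more than one linear map.
- **Focal loss**: `−α(1−p)^γ log p` for positives,
  `−(1−α)p^γ log(1−p)` for negatives, mean-reduced, predictions clipped at
  1e-7. At γ = 0, α = ½ it is half the binary cross-entropy.
- **GIoU**: `IoU − (|C| − |A∪B|)/|C|` with C the minimum enclosing
  axis-aligned box; continuous corner convention, area `(x2−x1)(y2−y1)`,
  no +1-pixel convention. Always ≤ IoU, equal when C is the union.

How a combined "focal + GIoU" detection objective weights the two terms is
a training-recipe question; the package provides the components and leaves
composition to the caller.

## Synthetic generators

`make_turtle_phantom` renders an analytic silhouette: body ellipse (full
axes default 240×160 px on a 480×640 canvas), head disc on the front tip
protruding by exactly `head_size`, thin tail ellipse protruding by
`tail_size`, and four limb discs placed to reach exactly the body
half-width. Membership is evaluated analytically per pixel in the rotated
body frame, so mask, centroid, heading and total extents
(length = major + head + tail, width = minor) are exact, with only ±1 px
rasterization slack. Body and background colors (olive ≈ (110, 115, 95) on
blue ≈ (40, 80, 210)) are validated at construction to straddle the color
model's threshold. Optional i.i.d. Gaussian pixel noise is seeded;
identical specs give byte-identical images. The phantom deliberately omits
texture, shadows, specular water sheen and limb articulation, so passing
tests demonstrate geometric correctness of the pipeline, not robustness to
real-world appearance variation.

`make_morphometric_dataset` draws the five lengths from a multivariate
normal (means 185/150/165/140/110 mm, SDs 15/12/13/12/10 mm, common
correlation 0.85 — shell measurements of farmed adults are strongly
size-correlated) and sets mass = −900 + 4·LP + 5.5·WP + 2.5·LF + ε with
ε ~ N(0, 43 g). The numbers are calibrated once so that masses span
roughly 390–1090 g (the range reported for farmed adult males) and the
population R² of the true law is ≈ 0.9, the regime in which the regression
module is meant to operate; the residual SD then also puts RMSE near 40 g.
Lengths are floored at 1 mm (a >10σ event) to keep records physical.

## Numerical choices and edge cases

- Empty masks raise degenerate-input errors everywhere rather than
  returning NaNs; a segmentation with no foreground aborts the pipeline
  with "no animal found".
- Closing rejects even kernel sizes; kernel 1 is the identity.
- Isotropy tolerance for θ: relative 1e-9 on `|a−c|` and `|2b|`.
- Heading skew threshold: standardized third moment below 1e-6 flags low
  confidence instead of guessing.
- Records warn (not error) when a width exceeds the paired length, since
  measurement protocols occasionally produce such records legitimately.
- MaxRE refuses records with zero mass instead of dividing by zero.
- All randomness flows through `numpy.random.default_rng(seed)`; no global
  state.

## Problem sizes

Unit tests use 240×320 phantoms and 16×16 random grids; the acceptance
suite sweeps 24–36 headings of the full 480×640 phantom, 200 random grids,
and 500 seeded regression replicates at n = 153. The whole suite runs in
about ten seconds on one core; `scripts/acceptance.py` in about five.

## Known limitations

- One animal per image; occlusion and multi-animal scenes are out of scope.
- The heading rule assumes a head-heavy asymmetry along the body axis; an
  animal with limbs and tail arranged to cancel the skew can be flipped.
- Box-extent widths slightly overestimate caliper widths on non-convex
  outlines.
- The linear mass law is a local approximation over the farmed size range;
  it is not a substitute for allometric power laws over wider ranges.
- No lens-distortion or perspective correction; the single scale factor
  assumes negligible board tilt.
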