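# Methods

## The measurement model

The corneal exposure ratio treats the cornea as the disc bounded by the
limbus (the iris/sclera border) and asks what fraction of that disc is
visible between the lids. The pipeline is:

1. **Segmentation.** The eye image is partitioned into skin, sclera,
   visible iris and visible pupil. The exposed-eye (palpebral-fissure)
   mask is the union of the within-fissure classes — visible iris ∪
   pupil ∪ sclera. This union is what "refining" the fissure mask with
   the scleral segmentation means operationally: it is the only
   composition for which intersecting with the full corneal disc yields
   exactly the visible cornea. The shipped reference segmenter is a
   nearest-palette classifier that is exact on synthetic imagery; real
   photographs require a trained backend implementing the
   `Segmenter` contract (image → `SegmentationMasks`). No weights are
   bundled and no training code exists here — the CER computation is
   backend-agnostic by design.
2. **Circle detection.** Pupil and iris circles are recovered with a
   circular Hough transform over the mask boundaries (default) or image
   edges. Each edge pixel votes for centres `a = x − r·cosθ`,
   `b = y − r·sinθ`, θ ∈ [0°, 360°), for every candidate radius.
3. **CER.** The full-iris mask sets every pixel whose centre satisfies
   the circle inequality to True; the cornea mask is its logical AND
   with the exposed-eye mask; the CER is the ratio of their non-zero
   counts × 100. The denominator is the *full* disc including the pupil
   region (the cornea overlies both), so exposed pupil pixels count as
   exposed cornea. Counting is by pixel-centre inclusion with no
   partial-pixel weighting.
4. **Calibration.** `mm_per_px = interlimbal_mm / (2·r_iris)` with the
   interlimbal (white-to-white) diameter defaulting to 11.7 mm, a
   standard adult population value. This affects reported lengths only,
   never the CER (a ratio).

## Coordinate and rasterization conventions

0-based pixel indices, origin top-left, y increasing downward. A pixel
belongs to a disc iff its centre satisfies `(x−cx)² + (y−cy)² ≤ r²`; a
pixel belongs to the aperture iff `y_u(x) ≤ y ≤ y_l(x)` at its centre.
Masks are hard binary — anti-aliasing would make ground truth
ill-defined.

## Hough transform numerics

- Candidate radii are the multiples of `radius_step` (default 1 px)
  inside `[radius_min, radius_max]`, defaulting to 5–45% of the smaller
  image dimension. θ is sampled every 1° by default.
- Votes are rounded to integer accumulator cells with **half-up**
  rounding (`⌊v + 0.5⌋`). Round-half-to-even would break translation
  equivariance at exact half-integer votes (e.g. r = 3, θ = 60° gives
  1.5); half-up commutes with integer image shifts.
- The peak acceptance threshold is `0.1 × 2πr` votes. Integer-cell
  rounding spreads the votes of a discrete boundary over neighbouring
  cells — a perfect full circle concentrates only ≈ 0.45·2πr votes in
  its peak cell — so this threshold leaves headroom to detect a circle
  from a surviving arc of one third, which is the detector's documented
  robustness target.
- Ties in support break deterministically by smaller radius, then
  smaller b, then smaller a. Non-maximum suppression measures Euclidean
  distance in (a, b, r) space (default separation 10): concentric
  pupil/iris peaks share a centre and must both survive.
- `locate_pupil_iris` narrows the radius search to ±5 px around the
  mask bounding-box half-width. Lids occlude from above and below, so
  the horizontal extent of a visible structure equals its diameter
  whenever the lateral limbus is open; the narrowing is an adaptive
  search window, disableable with `auto_radius_window=False`, and the
  full-range search remains the `hough_circles` default.
- Detection resolution is 1 px (no sub-pixel refinement). Because mask
  boundaries are *inner* boundaries, the fitted radius sits about half
  a pixel inside the true circle; the resulting CER error largely
  cancels between numerator and denominator and stays well under 1
  point in practice.

## Statistics

- **Paired t** and **one-way ANOVA** are the standard scipy routines
  behind the module surface. Identical paired series return (t=0, p=1)
  by convention; constant non-zero differences raise a
  degenerate-variance error instead of an infinite statistic.
- **ICC** is two-way, single-measure, computed from explicit variance
  components (row/column/residual mean squares). Absolute agreement is
  the default form — method comparison must penalize systematic offsets
  — with consistency available by flag. 95% CIs use the standard
  F-distribution bounds. Exactly identical series return ICC 1.0 by
  convention with a degenerate point interval, since the variance
  components collapse. Interpretation bands: 0.41–0.6 moderate, 0.6–0.8
  substantial, 0.8–1.0 excellent.
- **Bland–Altman** uses bias ± 1.96·SD (sample SD, n−1) with no
  small-sample t-correction, matching common practice for 95% limits of
  agreement.
- **Severity** is mild iff droop ≤ 2 mm, else moderate-to-severe; the
  **improvement rate** is 100 × (post − pre)/pre on group means,
  reported to two decimals.
- Two eyes of one patient are treated as independent observations;
  per-patient clustering (mixed models) is out of scope.

## The synthetic generator

The generator emulates a cropped frontal eye: circular iris with
concentric pupil, almond-shaped fissure bounded by two parabolic lid
curves meeting at canthi placed at ±1.4·r horizontally at iris-centre
height, flat-color tissue classes with optional Gaussian intensity
noise. Defaults: 256×256 raster at 0.1 mm/px, hence an iris radius of
58.5 px (11.7 mm interlimbal diameter exactly); lower lid apex at
0.95·r below centre; upper lid apex at the superior limbus for zero
droop, lowered by `droop/mm_per_px` pixels per millimetre of droop.
Cohorts draw droop uniformly from 0–8 mm, sweeping the true CER over
roughly 33–100% and covering both severity classes; ground truth is
exact pixel counting on the painted masks.

What it does **not** emulate: photographic texture, specular
highlights, eyelashes, iris color variation, non-circular limbus,
head-pose or perspective distortion, 3-D globe curvature. Passing tests
therefore demonstrate correctness of the geometry, voting and
statistics — not segmentation robustness on clinical photographs, which
lives entirely in the (pluggable) trained backend.

## Problem sizes

The validation cohort is 100 eyes at 256×256 px — large enough for
stable agreement statistics and a ≥ 30-point CER spread, small enough
that the whole suite runs in well under a minute on one core.
Hough-oracle equivalence checks use ≤ 32×32 rasters where the
exhaustive accumulator is tractable.

## Known limitations

- Pupil localization degrades under severe droop (lid below pupil
  centre leaves only a thin pupil sliver); the pupil then falls back to
  a flagged synthetic circle at 0.4·r_iris. The CER itself never uses
  the pupil circle.
- At the extreme of the droop range (~8 mm, CER ≈ 30%) the iris fit can
  drift 2–3 px because the lid-margin chord competes with the short
  limbal arc; cohort-level mean absolute error stays well inside 2 CER
  points.
- No exclusion of specular highlights or lash occlusion from the cornea
  mask: such pixels, if a backend labels them outside the fissure
  classes, simply reduce the exposed mask.
- 2-D analysis only; no ellipse fitting for off-axis gaze.
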