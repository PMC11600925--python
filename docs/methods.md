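# Methods

This note documents the models, conventions and numerical choices behind
`kneetemplate`, and what its synthetic validation does and does not show.

## Coordinate conventions

All templating runs in a calibrated millimetre frame with y increasing
proximally ("upward" on an upright radiograph). Raster input (pixels, y
down) is converted at ingestion: `x_mm = x_px * s`, `y_mm = (H - y_px) * s`
with `s` the marker-derived scale and `H` the image height. A single
isotropic scale per image is assumed (a ruler or sphere marker yields one
scale; no per-axis magnification or distortion model). Mechanical and
anatomical axes are directed *distally*; medial is derived per scene from
the plateau landmark pair, never from image left/right, so left and right
knees need no special-casing.

## Coronal plan

* FMA: femoral head center → trochlear groove. TMA: midpoint of the
  plateau edge landmarks → talar dome center.
* HKA is the signed angle between the two distal directions; the sign is
  varus-positive, decided by whether the tibial direction deviates toward
  the medial unit vector. This is side-agnostic.
* Femoral cut: perpendicular to the FMA, 9 mm (configurable) proximal to
  the most distal condylar contour point, matching the implant's distal
  thickness. No femoral angular adjustment is applied; the source workflow
  describes an adjustment only for the tibial component.
* Tibial cut: perpendicular to the TMA, 10 mm (configurable) distal to the
  most proximal plateau contour point. Resection depth per side is
  measured *parallel to the TMA* from that side's plateau landmark to the
  cut — the axis-parallel depth matches how resection is read
  intraoperatively. The "lesser side" is whichever side has the smaller
  depth (medial in varus, lateral in valgus); if its depth is < 2 mm the
  cut is rotated about its intersection with the TMA so the MPTA becomes
  88°, with the tilt direction chosen to deepen the lesser side. The
  adjustment is applied once; the residual depth is reported, not
  re-iterated. Pivoting on the axis keeps the overall resection level
  anchored while only the tilt changes.
* Insert points are the *outermost* pair of cut/contour crossings: with
  concave contours (intercondylar notch, osteophyte lobes) more than two
  crossings occur, and the implant borders are the cortical edges.

The 9 mm femoral and 10 mm tibial offsets are both exposed as parameters
because the two figures of the source workflow print different values for
"the" resection offset; the defaults keep each as printed.

## Sagittal plan

* The anterior cortical line is a total-least-squares (principal-axis) fit
  to per-scanline anterior-most boundary samples in a window 20–80 mm
  proximal to the most distal femoral point (window start/length and the
  2 mm scanline band are configurable). The contour boundary is resampled
  at ~1 mm arc length first: simplified polygons carry no vertices along
  straight cortex stretches, and a vertex-only scan would see nothing
  there. Femoral AP length is the maximum perpendicular distance from that
  line over contour points posterior to it; the implant's anterior flange
  is flushed to the cortex (notch avoidance), so no anterior offset is
  added.
* The tibial anatomical axis passes through the two shaft landmarks. The
  tibial cut starts perpendicular to it 10 mm distal to the highest
  plateau point and is rotated about its axis crossing by the posterior
  tibial slope (default 3°), with the rotation sign chosen so the
  posterior end drops. The slope is configurable because the 3° target
  assumes a posterior-stabilized design.

## Size selection

The chart lookup is a floor rule: the largest size whose chart dimension
does not exceed the measured width. Rounding to the nearest size could
overhang, and overhang prevention is the governing principle of the merge
rule (`merged = min(coronal, sagittal)`), so the floor convention is
applied consistently. Widths outside the chart clamp to the end sizes with
`undersized_bone` / `oversized_bone` flags. The shipped chart is synthetic:
eight sizes with uniform steps (femoral ML 58 + 2.5·(k−1), AP 52 +
2.2·(k−1); tibial ML 61 + 2.6·(k−1), AP 40 + 1.8·(k−1) mm), spaced like a
typical contemporary primary-TKA system but not vendor data.

## Synthetic anatomy

The generator emulates the statistical structure the pipeline assumes, not
radiographic appearance. Shapes are piecewise line/arc silhouettes chosen
so every measured quantity has a closed form:

* AP femur: two condylar arcs (radius 23 mm) whose centers are placed so
  the chord 9 mm above the distal surface equals the requested ML width
  exactly: `W(9) = 2d + 2*sqrt(R² − (R−9)²)` for centers at ±d.
* AP tibia: a plateau whose sides flare at 0.6 mm/mm, giving the 10 mm
  chord `W_top + f·10 + f·(10 − a)` with medial attrition `a` lowering the
  medial corner; `W_top` is solved from the requested width.
* Lateral femur: straight anterior cortex plus a posterior condylar circle
  whose posterior reach *is* the AP length.
* Lateral tibia: a rectangular upper segment, so the sloped chord is
  `depth / cos(slope)`.

A single truth object drives both views. The deformity is imposed by
rigidly rotating the tibia (with its landmarks) about the plateau midpoint
by the HKA angle; the whole scene then receives a small random rotation
(±2°) and translation so nothing stays axis-aligned. Contour noise is
i.i.d. uniform vertex perturbation; at noise amplitudes above the vertex
spacing the boundary is first decimated to ≥ 2.8× the amplitude so the
jitter cannot fold it (validity is checked and re-drawn if needed).
Landmark jitter is independent uniform perturbation of each landmark.

Default cohort distributions mirror a varus-dominant osteoarthritis
population (≈78% varus > 3°, ≈14% valgus, right knees 54%), mid-range
sizes most common, image scale 0.12–0.20 mm/px, contour noise 0.3 mm and
landmark jitter 0.5 mm as plausible segmentation/detection error. Medial
attrition grows with varus and is capped at 7.5 mm because severely
attritioned knees are excluded from the standard templating workflow; the
0–12 mm attrition sweep exercises the 88° rule explicitly. Bone widths are
drawn uniformly within the 15–85% band of the true size's chart bin — a
"size-k knee" is one whose bone lies in size k's bin, not one sitting on a
bin boundary.

What passing synthetic tests shows: the geometry, rules, merge logic and
statistics are implemented correctly, and the pipeline is robust to
segmentation-scale noise. What it does not show: performance on real
radiographs, whose contours carry osteophytes, overlap shadows and
systematic segmentation bias that no vertex-jitter model reproduces.

## Evaluation

* The agreement taxonomy counts "accurate" inclusively (exact or within
  one size), matching the standard templating convention.
* Quadratic-weighted kappa is computed from the observed table and the
  marginal-product expectation, `κ = 1 − Σw·O / Σw·E`,
  `w_ij = (i−j)²/(k−1)²`; an all-one-category table raises an
  undefined-kappa error. A qualitative band (poor … almost perfect) is
  emitted alongside the value.
* Registration fits scale and translation by least squares on marked point
  pairs with rotation held fixed, then picks the rotation maximizing mask
  overlap: a 1° grid over ±20° followed by golden-section refinement to
  0.05°. The overlap score is the mean bilinearly interpolated pre-mask
  value at transformed post-foreground pixels (up to 25k samples); with
  radiograph-resolution masks this recovers rotation to ≈0.15° worst-case,
  which dominates the translation error through the points' lever arm.
* Positioning error compares insert-point midpoints, except the lateral
  femoral component, where the most posterior implant point's offset from
  the anterior cortical line is compared; alignment error is the angle
  between the predicted reference line and the marked implant baseline.

## Numerical choices

* Angles between lines use `atan2(|cross|, |dot|)`: near-parallel
  configurations lose ~1e-6° through `acos`, which matters when asserting
  exact 0°/90° constructions.
* Line–polygon intersection solves each edge parametrically and
  deduplicates crossings within 1e-6 mm (vertex grazes); results sort
  along the line. Extremes of linear functionals are taken over vertices
  only (they cannot occur in edge interiors); ties break to the lowest
  vertex index for determinism.
* The rotated-line helper re-anchors at the pivot, which for on-axis
  pivots (the only pipeline use) equals the rigid rotation of the line.
* Degenerate inputs raise named errors (coincident axis landmarks,
  resection lines missing the bone, empty masks, underdetermined
  transforms); the pipeline wraps them with the stage name.

## Problem sizes

The shipped validation uses 1,000 random polygons for the geometric
oracles, a 48-point attrition sweep, 200 noiseless and 500 noisy knees for
size recovery, 100 random tables for kappa, and 100 synthetic transforms
for registration; the full suite and the acceptance script each run in
well under a minute on one CPU.

## Known limitations

Single isotropic calibration (no distortion model); no valgus-specific
femoral adjustment rules; no patellar component; the lateral-femur AP
length uses the full distal contour maximum without distinguishing medial
from lateral condyle silhouettes; size charts must be user-supplied for
real implant systems; and the synthetic generator makes no claim of
anatomical realism beyond the features listed above.
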