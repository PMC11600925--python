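# kneetemplate

Automated two-dimensional digital templating for total knee arthroplasty
(TKA): from calibrated bone contours and anatomical landmarks to merged
implant-size predictions, resection-line placement, and the statistics used
to validate them.

## The problem

Before a TKA, surgeons template the knee on plain radiographs: they draw the
mechanical axes, place the planned bone cuts, and read off which implant
size fits the bone without overhanging the cortex. Done by hand this takes
minutes per knee and is a common source of size mismatches discovered
mid-surgery. `kneetemplate` implements the geometric calculation layer of an
automated templating pipeline. Segmentation and landmark detection are the
job of an upstream model (or a human annotator); this package consumes their
output — binary bone masks and named landmark points, plus a calibration
marker of known physical size — and produces a complete, reproducible plan.

## The method

All computation happens in calibrated millimetres (a two-point marker of
known separation fixes the mm/pixel scale, counteracting radiographic
magnification). Writing FMA/TMA for the femoral/tibial mechanical axes:

* **Coronal (AP view).** FMA runs from the femoral head center to the
  trochlear groove; TMA from the midpoint of the tibial plateau edges to the
  talar dome center. Their signed angle is the hip–knee–ankle angle (HKA,
  varus positive). The femoral cut is the perpendicular to the FMA 9 mm
  proximal to the most distal condyle point; the tibial cut the
  perpendicular to the TMA 10 mm distal to the highest plateau point
  (medial proximal tibial angle, MPTA = 90°). The outermost intersections of
  each cut with the bone contour are the medial/lateral insert points; their
  separation is the mediolateral (ML) width. If attrition or varus leaves
  the lesser side with < 2 mm of resection, the tibial cut is re-tilted to
  MPTA = 88° toward deeper resection on that side and re-measured.
* **Sagittal (lateral view).** The anterior cortical line of the distal
  femur is fitted to the shaft cortex (flushing the implant flange to it
  avoids femoral notching); the femoral AP length is the longest
  perpendicular distance from that line to the distal condyle. The tibial
  cut is placed 10 mm below the plateau and tilted to a 3° posterior tibial
  slope (PTS) about the tibial anatomical axis; its outermost contour
  crossings give the tibial AP width.
* **Size selection.** Each view recommends the largest catalogue size whose
  ML (coronal) or AP (sagittal) dimension still fits within the measured
  width; the merged prediction is the *lesser* of the two, preventing
  overhang. The shipped eight-size chart is synthetic (vendor charts are
  proprietary); supply your own as CSV `component,size,ml_mm,ap_mm`.
* **Validation tooling.** Agreement taxonomy (exact / accurate-within-one /
  over- / underestimate), Cohen's kappa with quadratic weights, and a
  postoperative registration procedure (scale+translation from marked point
  pairs, rotation by maximizing mask overlap) with insert-point positioning
  errors.
* **Synthetic anatomy.** A seeded parametric generator builds AP and
  lateral knee silhouettes from line/arc primitives with analytic ground
  truth for every measured quantity — deformity, medial attrition,
  magnification, contour noise and landmark jitter are all controllable —
  so the entire pipeline is testable end-to-end without patient data.

## Worked example

```python
from kneetemplate import (template_knee, generate_truth,
                          generate_ap_scene, generate_lat_scene)

truth = generate_truth(7, noise_mm=0.3, landmark_jitter_mm=0.5)
ap, _ = generate_ap_scene(truth)
lat, _ = generate_lat_scene(truth)
res = template_knee(ap, lat)
cor, sag = res.coronal_plan, res.sagittal_plan
print(f"femoral: ML {res.femoral.coronal_width_mm:.1f} mm -> size "
      f"{res.femoral.coronal_size}; AP {res.femoral.sagittal_width_mm:.1f} "
      f"mm -> size {res.femoral.sagittal_size}; merged {res.femoral.merged_size}")
print(f"HKA {cor.hka_deg:.2f} deg, MPTA {cor.mpta_deg:.1f} deg "
      f"(adjusted={cor.mpta_adjusted}), PTS {sag.pts_deg:.0f} deg")
```

prints

```
femoral: ML 64.1 mm -> size 3; AP 57.8 mm -> size 3; merged 3
HKA -4.24 deg, MPTA 90.0 deg (adjusted=False), PTS 3 deg
```

i.e. this (valgus, HKA −4.2°) knee measures 64.1 mm mediolaterally at the
9 mm femoral station and 57.8 mm anteroposteriorly from the cortical line —
both inside the size-3 bin of the chart — so both views agree and the
merged femoral prediction is size 3. The tibial cut kept its neutral 90°
MPTA because the lesser (medial) side still gets 9.5 mm of resection.

The same pipeline runs file-to-file from the command line:

```sh
kneetemplate simulate --n 10 --seed 1 --out cohort/
kneetemplate template --ap-dir cohort/knee_000/ap --lat-dir cohort/knee_000/lat \
    --chart cohort/chart.csv --out report.json
kneetemplate evaluate --pred pred.csv --actual cohort/actual.csv --out agreement.json
```

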