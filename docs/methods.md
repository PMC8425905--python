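# Methods

## Quantities

**Water-equivalent diameter.** A patient cross-section with pixel HU
values `HU_i` inside a body ROI has water-equivalent area
`A_w = sum_i (HU_i/1000 + 1) * a_px` (with `a_px` the physical pixel
area in cm²), i.e. each pixel is weighted by its attenuation relative to
water (HU 0 counts fully, air HU -1000 counts zero). D_w is the diameter
of the water disc with that area:

    D_w = 2 * sqrt(A_w / pi)
        = 2 * sqrt( (mean_HU/1000 + 1) * A_ROI / pi )

The two forms are algebraically identical; the implementation uses the
per-pixel sum (see *Numerical choices*). Per-slice D_w values are
averaged (unweighted) over the series.

**SSDE.** `SSDE = CTDIvol * f_size(D_w)` with
`f_size = a * exp(-b * D_w)`, the AAPM Report 204 exponential fits
(body 32-cm reference: a = 3.704369, b = 0.03671937; head 16-cm:
a = 1.874799, b = 0.03871313). The coefficients ship as a JSON config
(`ctsize/data/size_conversion.json`) so alternative tables can be
dropped in. Outside the fitted 6–55 cm range the curve is extrapolated
with a warning. The series SSDE evaluates f_size at the series-mean
D_w; per-slice SSDE values (per-slice D_w with per-slice CTDIvol, else
the series CTDIvol) are additionally written to the CSV report, since
sources differ on which convention scanners use. When per-slice CTDIvol
values disagree, the series value is their mean (logged).

**Algorithm comparison.** `delta(%) = (new - old)/old * 100`, applied
to series-mean D_w and SSDE. In `--algorithm both` mode both contours
run on the identical thresholded input, so the difference isolates the
contouring rule alone.

## Contouring

Threshold at -200 HU (inclusive: a pixel at exactly -200 HU is tissue),
8-connected component labeling, per-component outer-contour filling
(`binary_fill_holes`; 4-connected background is the correct dual of
8-connected foreground, so diagonal pixel chains still enclose holes),
retention of the six largest filled components, then couch removal:
any retained object whose filled-region centroid row exceeds
`round(400 * n_rows / 512)` is discarded. If nothing survives the couch
rule the slice is rejected ("no patient found above table line"). The
legacy algorithm differs only in keeping the single largest surviving
component.

Parameter defaults and the reasons they are exposed:

| parameter | default | unit | notes |
|---|---|---|---|
| `threshold_hu` | -200 | HU | separates tissue (≥ ~-120) from air/lung-free background; inclusive comparison |
| `k_objects` | 6 | – | enough for torso + 2 arms/legs + stray objects; fewer components ⇒ all kept |
| `table_y_limit_px` | 400 | px of a 512-row image | couch sits in the lower fifth of the field; some sites may need 450 |
| `phantom_ref` | body-32cm | – | `head-16cm` for head protocols |

Tie-breaks: equal filled areas rank by ascending label (labels are
assigned in raster order, so this is deterministic). A retained
component may extend below the couch line (large patients touch the
couch pad); the centroid decides and a warning is logged. A couch that
*touches* the body would merge into one component and be retained the
same way — the generator keeps them disjoint, so this path is only
logged, never exercised by the tests.

## Synthetic phantoms

Scenes are unions of axis-aligned ellipses on a -1000 HU background:
soft tissue 40 HU, lung cavities -800 HU, couch strip 200 HU — values
chosen to sit unambiguously on either side of the -200 HU threshold.
Five scene classes cover the contouring regimes: one substantial object
(`pelvis`; `chest_arms_up` with two lung holes), two objects
(`chest_one_arm_down`, `two_legs`) and three (`chest_two_arms_down`).
Default raster: 512×512 at 0.8 mm pixels (40.96 cm field). `size_scale`
(0.5–1.5) scales all body dimensions about the scene centre; a seeded
jitter (≤3% on axes, ≤4 mm on the scene centre) individualizes cohort
members. Base dimensions were fixed once so that every scene stays
inside the grid and off the couch strip across the whole scale range,
and inter-object gaps stay above 2 px at the smallest scale (so
8-connectivity never fuses parts). The couch is not scaled.

Rasterization is pixel-centre point-in-ellipse with no anti-aliasing:
the discrete mask is unambiguous, rendering is bitwise deterministic,
and the O(h/√A) area error of a half-pixel boundary band is analyzable —
measured, the pipeline-vs-analytic D_w deviation stays below 0.12% over
all scenes and scales (bound used in tests: 0.5%).

The analytic oracle needs no rasterization: ellipse areas are `pi*a*b`,
the mean HU is the area-weighted mean of the constituent regions
(cavities at their own HU), and D_w follows in closed form. It assumes
bodies are pairwise disjoint and cavities nested, which the generator
validates (grid containment exactly; cavity containment by 64-point
boundary sampling).

What the phantoms do **not** emulate: noise, texture, beam hardening,
partial-volume boundaries, non-elliptical anatomy, couch shapes other
than a strip, and bodies touching the couch. Passing tests therefore
demonstrate the correctness of the geometry/attenuation pipeline, not
segmentation robustness on clinical images; the -200 HU threshold in
particular is taken as given, not re-validated here.

## Numerical choices

- D_w uses the per-pixel water-equivalent sum rather than the
  mean-HU form. `-1000/1000 + 1` is an exact float `0.0`, and such
  zero terms are dropped before summation; consequently enlarging an
  ROI by pure-air pixels leaves D_w *bitwise* unchanged regardless of
  summation order. The defining equation
  `dw² · pi/4 = (mean_HU/1000 + 1) · A_ROI` then holds to float
  round-off (tested at 1e-9 relative).
- HU grids are floored at -1024 on ingestion (scanner padding guard);
  a mean HU below -1000 (negative radicand) is a hard error.
- DICOM serialization stores HU as unsigned 16-bit with slope 1 /
  intercept -1024, so synthetic integer-HU scenes round-trip exactly
  (≤1 HU in general).
- Slices order by ImagePositionPatient z when available on all files,
  else InstanceNumber, with the file name as final tie-break —
  deterministic for a fixed input.

## Verification problem sizes

The shipped verification (`scripts/acceptance.py` and the end-to-end
tests) uses 20 water ellipses for the oracle-agreement bound, 40
mixed-scene phantoms for the automated-vs-oracle R², 100 random scenes
for the per-pixel-summation equivalence, and 20 single-object chest
scenes for the old/new zero-difference check — cohort sizes at which
every statistic is stable to well inside its tolerance while the whole
suite runs in seconds.

## Known limitations

- Single-frame CT Image Storage only; no multi-frame/enhanced DICOM,
  compressed transfer syntaxes beyond pydicom's native support, or PACS
  networking.
- No localizer-based D_w, no effective-diameter (D_eff) path, no organ
  dose.
- The couch rule is positional; a couch rendered above the scaled
  400-px line (unusual FOVs) would not be removed.
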