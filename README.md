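# shellmetrics

Image-based morphometry and mass prediction for single animals photographed
on a uniform colored background — built around the measurement workflow used
for sorting farmed Chinese softshell turtles (*Pelodiscus sinensis*) by
weight.

Weighing every animal by hand is slow and stressful for the stock. Shell
dimensions predict body mass well, and shell dimensions can be measured from
a photograph: segment the animal from the board, find its orientation,
rotate it to a canonical pose (body axis horizontal, head left), convert
pixel extents to millimetres with a reference object, and feed the lengths
into a fitted linear mass model.

## What's inside

| stage | module | core idea |
| --- | --- | --- |
| segmentation | `shellmetrics.segmentation` | threshold `I = Cr·R + Cg·G + Cb·B` with `ΣC = 0` (brightness-invariant chroma score), then binary closing |
| contours | `shellmetrics.contours` | Suzuki–Abe border following: outer/hole boundaries with NBD labels and hierarchy, plus an exact rasterizing inverse |
| pose | `shellmetrics.pose` | image moments → centroid and `θ = ½ atan2(2b, a−c)`; heading disambiguated by axis skewness; rotation to the standard state |
| morphometry | `shellmetrics.morphometry` | scale factor `s = Lb/Lbp` (mm/px), bounding-box extents, the five shell parameters LC, WC, LF, LP, WP |
| mass model | `shellmetrics.mass_model` | OLS fit `M = β₀ + Σβᵏxᵏ`; metrics R², MAE, MSE, RMSE, MaxRE |
| detector math | `shellmetrics.nn_components` | SimAM energy attention, SE channel gating, focal loss, GIoU — pure numpy |
| synthetic data | `shellmetrics.synthetic` | seeded turtle phantoms and measured populations with exact ground truth |
| pipeline + CLI | `shellmetrics.pipeline`, `shellmetrics.cli` | one-command runs with per-stage artifacts |

## Worked example

Render a synthetic turtle at heading 139.11°, measure it, then fit a mass
model on a synthetic measured population and predict:

```sh
$ shellmetrics simulate phantom --heading 139.11 --out-dir .
wrote phantom at heading 139.11 deg to .

$ shellmetrics run --img phantom.png --out-dir out --scale-mm 60 --scale-px 120
{"xc": 327.4427825193389, "yc": 246.44832015528218, "theta_deg": 139.08397381033376, "heading_deg": 139.08397381033376, "low_confidence": false}
     id  LC_mm  WC_mm LF_mm LP_mm WP_mm mass_g
phantom  153.0   81.0  None  None  None   None
```

The estimated heading (139.08°) recovers the generator's 139.11° to 0.03°.
With the 60 mm reference spanning 120 px the scale is 0.5 mm/px; the
standardized silhouette spans 306×162 px, i.e. 153.0×81.0 mm, matching the
phantom's analytic ground truth (305×160 px) within rasterization slack.
The ventral-view fields stay `None`: a dorsal photograph cannot yield them.

```sh
$ shellmetrics simulate population --seed 7 --out pop.csv
wrote 153 records to pop.csv

$ shellmetrics fit --records pop.csv --predictors LP,WP,LF --out model.json
{"predictors": ["LP", "WP", "LF"], "intercept": -850.7646901834594, "coefficients": [2.9805817265779764, 5.817509970476896, 2.8445400200472157]}
R2=0.889 MAE=32.41 g RMSE=40.63 g MaxRE=19.06% (n=153)

$ shellmetrics run --img phantom.png --out-dir out --model model.json --view plastron
predicted mass: 511.7 g
```

The population generator plants the law `M = −900 + 4·LP + 5.5·WP + 2.5·LF`
plus 43 g of noise; the fit recovers coefficients within sampling error and
reports R² ≈ 0.89 — the regime this kind of shell-to-mass model operates in.
Every run writes its intermediate artifacts (mask, contours JSON, pose
JSON, standardized image, record CSV) under `out/`.

The same operations are available as library calls; see the docstrings in
each module and `docs/methods.md` for the underlying models, conventions
and their assumptions.

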