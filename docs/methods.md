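# Methods

This note records what each estimator in `semmorph` actually computes,
the defaults and their rationale, the numerical choices that matter,
and what the synthetic fixtures do and do not establish about real
micrographs.

## Calibration and segmentation

All physical quantities derive from a single user-supplied pixel size
(µm/pixel). SEM vendors embed scale information in nonstandard tags,
so no metadata parsing is attempted; the calibration is an explicit
argument and is carried on every object. Multi-channel inputs are
reduced by the unweighted channel mean (the SEM signal is physically
single-channel).

Thresholding defaults to Otsu's method — parameter-free, hence
reproducible across analysts — with a manual threshold for
low-contrast material (foreground is `v > t` for Otsu, `v ≥ t` for
manual, so a manual threshold of 0 selects everything; `invert` flips
the side for dark-on-bright material). A zero-variance image is a
degenerate input for Otsu and raises an error advising a manual
threshold. Mask cleaning removes connected components strictly smaller
than `min_object_px` (default 25 px, the same floor below which width
estimation is unreliable) and optionally fills interior holes.

Instances are 8-connected components by default: thin neurites
rasterise with diagonal steps that 4-connectivity would fragment.
Cells touching the raster border are flagged and excluded from
morphometry by default (their dimensions are censored); whole-field
fractal/texture analyses keep them. Outlines are marching-squares
contours (sub-pixel, ordered); multiply-connected instances keep the
outer contour.

## Rod morphometry

The rod model is a spherocylinder of total length L (hemispherical
caps included) and width W:

* volume V = (πW²/4)(L − W/3), which reduces to the sphere πd³/6 at
  L = W;
* model surface S = πWL (cylinder side πW(L − W) plus cap area πW²).
  S is a model-based 3-D quantity and is reported separately from the
  2-D projected area (pixel count × pixel area) — a single projection
  cannot measure a true 3-D surface, so both are emitted and labelled.

Length and width come from the medial axis of the silhouette:

* **Length** — the longest geodesic path through the medial-axis
  graph, extended at both ends by the local medial radius. Path length
  is measured on the pixel path resampled every 5 px and summed as
  Euclidean segments: the raw 8-connected chain length overestimates a
  straight digital line by up to 8 % at worst-case orientation
  (mean ~5.5 % over orientations), while the resampled polyline is
  accurate to well under 1 % whenever the curvature radius exceeds a
  few pixels. The same rule is used for neurite lengths.
* **Width** — twice the mean medial radius over the *cylindrical
  trunk* of that path. Radii sampled closer to either path end than
  their own value (plus 2 px of rasterisation slack) lie inside the
  hemispherical end caps, where the medial radius tapers; including
  them biases the mean low. A near-circular cell is all cap — the
  trunk is then empty and the width falls back to twice the maximal
  inscribed radius, so a disc of diameter d reports length ≈ width ≈ d.
  The mean (not the maximum) trunk radius is used because the
  spherocylinder underlying V assumes constant width.
* All medial radii are corrected by −0.5 px: the Euclidean distance
  transform measures centre-to-centre distances and overestimates the
  half-width of a rasterised solid by half a pixel per side.
* `medial_axis` is called with a fixed tie-break RNG; its default
  randomised thinning order would make repeated measurements of the
  same mask differ in the last digits.

Instances under 25 px (configurable) are rejected rather than
measured: below this, distance-transform width quantisation exceeds
~10 %. Cells measuring wider than long are rejected by the volume and
surface formulas (the model assumes a rod); the measurement layer
clamps marginal W > L cases arising from noise (ratio ≤ 1.1) with a
warning. On generated rod populations the estimators recover L within
~2 % and W within ~4–5 %; the residual ~2 % downward bias of W/L is the
discretisation study's expected scale for 30–50 px wide rods.

Optional Feret-style output (bounding-box diagonal) is emitted as a
crude cross-check only.

## Neuronal descriptors

* **Soma** — maximal inscribed disc: centre at the distance-transform
  argmax (ties broken deterministically to the lowest row, then
  column, with a warning), diameter twice the maximum distance value.
  Parameter-free and matches the intuitive "cell body" of
  neuroblastoma silhouettes.
* **Neurites** — the silhouette is skeletonised; skeleton pixels
  inside the soma disc are removed; each remaining 8-connected
  component adjacent to the soma (its anchor chosen as the touching
  pixel nearest the soma, ties lexicographic) yields one trace, whose
  path is the longest geodesic from the anchor to a skeleton endpoint.
  A branched subtree therefore counts once, its longest branch
  defining the length. For a round-capped process the medial axis
  terminates at the cap centre, so the geodesic length matches the
  centreline length. Traces shorter than `min_neurite_um` (default
  5 × pixel size, i.e. 5 px) are discarded as skeletonisation spurs.
* **Radial distance** — Euclidean base-to-tip distance of the trace;
  the base is the trace anchor at the soma *boundary* (an alternative
  reading — distance from the soma centre — is not used; switch by
  measuring from `soma_center` if needed). **Straightness** is length
  minus radial distance (≥ 0 by the triangle inequality, clipped at 0
  against float noise); a dimensionless tortuosity (length/radial) is
  emitted as a labelled extension.
* **Alignment** — the tip-base chord angle is folded into [0°, 90°]
  relative to a reference axis (default 0° = image x-axis; a seeded
  random axis mode exists for unpatterned substrates). Classes:
  parallel < 15°, perpendicular > 75°, the unnamed middle band is
  called *intermediate*; the boundary angles themselves are
  intermediate (strict inequalities).
* **Circularity** — C = 4πA/P² with A the pixel count × pixel area.
  The perimeter estimator is the deliberate choice here: a literal
  boundary-pixel count overestimates smooth perimeters by ~26 %
  (C(disc) ≈ 0.62) and the √2-weighted contour chain by a provable
  (8/π)(√2 − 1) ≈ 5.5 % (C(disc) ≈ 0.90) — both contradict the
  calibration point that a round cell has C = 1. The default is the
  Crofton-formula estimator (4 directions), which is accurate to < 1 %
  on discs (measured: C = 0.998 at r = 200 px); `chain` and
  `pixel_count` remain available for literal comparability with
  pixel-counting protocols. Rasterised discs may land marginally above
  1; the documented allowance is ε_raster = 0.05.
* **Differentiation** — a cell counts as differentiated when its
  longest neurite is at least the soma diameter; cells without
  neurites never count. Averages over zero neurites are reported as
  undefined (None), not 0.

Recovery on generated neurons: neurite count exact, arm lengths within
5 % (dominated by the ~1–2 px anchor offset at the soma boundary),
chord angles within 1°, straightness ≤ 2 % of length for straight
arms.

## Fractal analysis

Box counting uses box sides in powers of 2 from 2 px to a quarter of
the smaller image dimension (≥ 4 sizes required; configurable), and
for each size reports the minimum box count over a set of grid phases:
`n_offsets` = 4 evenly spaced diagonal translations *plus one phase
anchored at the foreground bounding-box corner*. The anchor matters:
evenly spaced phases alone leave the count sensitive to where the
pattern sits (a translated Sierpinski gasket loses ~0.15 in D), while
the anchored phase realigns the grid exactly under any translation or
90° rotation, making D invariant by construction. Increasing
`n_offsets` only ever lowers counts (minimum over a superset).

D is the unweighted least-squares slope of log N versus log (1/ε); the
fit R² is always reported and a warning is emitted below 0.98 (poor
scaling regime). Analysis runs on filled silhouettes by default, with
an outline-only mode (1-px boundary) for outline-based protocols.
Calibration: line → D = 1, filled square → D = 2, dyadic Sierpinski
gasket (2^k canvas, 3^k pixels) → D = log 3/log 2, all exact to the
fit.

Lacunarity is the gliding-box estimator: box masses M over every
window position (exact integer window sums via an integral image),
Λ(r) = var(M)/mean(M)² + 1, so a translationally uniform pattern gives
exactly 1 and Λ ≥ 1 always; a non-overlapping `grid` mode exists for
comparability. The normalisation (+1 convention) is stated because the
literature is split between var/mean² and E[M²]/E[M]² forms, which
differ by exactly this constant.

## GLCM texture

Intensities are quantised by uniform binning of the full bit-depth
range — not the observed min–max — so descriptors are comparable
across micrographs from one acquisition session; a constant offset
smaller than one bin leaves all descriptors unchanged. Default
configuration: 16 levels, the four distance-1 offsets
{(0,1), (1,0), (1,1), (1,−1)} accumulated, symmetrised, normalised to
sum 1 (a rotation-tolerant default; all configurable).

The five descriptors follow the classical Haralick definitions: ASM =
Σp², entropy = −Σ p ln p (natural log by default, log₂ optional),
contrast = Σ(i−j)²p, correlation = Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ), IDM =
Σ p/(1+(i−j)²). "Inverse different moment" is read as the standard
inverse difference moment. For a single-valued (quantised) image the
marginal σ vanishes and correlation is reported as undefined (None, or
NaN in map rasters) rather than propagating NaN through arithmetic.
Analytic anchors: constant image → (ASM, entropy, contrast, IDM) =
(1, 0, 0, 1); period-1 checkerboard at offset (0,1) →
(0.5, ln 2, 1, 0.5) with correlation −1.

`texture_map` slides a window (default 64 px, stride 32) over the
once-quantised image and emits one raster per descriptor — the feature
maps a downstream classifier would consume; classification itself is
out of scope.

## Synthetic fixtures

The generators are pure functions of (parameters, seed) — one
`numpy.random.Generator` per call, no global state — so regeneration
is bit-identical.

* **Rods**: spherocylinders (all pixels within W/2 of an axis segment;
  L includes the caps) placed by rejection sampling with a 2-px
  separation margin so instances stay distinct under 8-connectivity.
  The `ecoli` preset draws lengths uniform on 2–4 µm with constant
  aspect ratio 0.25 and isotropic orientation at 0.02 µm/px —
  sub-µm-wide rods with ≥ 25 px across the thinnest cell. Foreground
  180 on background 20 (8-bit) with optional additive Gaussian noise.
* **Neurons**: soma disc plus thick polyline arms at 0.2 µm/px;
  tortuosity is a perpendicular sinusoid of given amplitude (three
  periods per arm). Ground truth records each arm's *drawn centreline*
  arc length and chord angle; overlapping arms are rejected.
* **Fractals**: deterministic line, filled square, and the dyadic
  Sierpinski gasket (canvas 2^k, exactly 3^k foreground pixels).
* **Textures**: constant, checkerboard, stripes, Gaussian noise;
  constant and period-1 checkerboard carry their closed-form GLCM
  descriptors in the ground truth.

Fixture sizes are desk-scale by design: rod-field acceptance runs use
n = 50 rods on a ~1.8k² canvas, fractal calibration a 512-px canvas —
large enough that discretisation errors sit well inside the stated
tolerances, small enough that the full suite runs in seconds. What
passing these tests shows is that the *geometry and statistics* of the
estimators are correct; the fixtures do not emulate SEM rendering
(charging artefacts, topographic shading, focus drift), touching or
overlapping cells, or debris, so real micrographs may still need
manual threshold choice and careful instance separation upstream of
these descriptors.

## Known limitations

* Touching cells are measured as one connected component; there is no
  watershed or learned instance splitting.
* The rod width assumes an approximately constant-caliber body;
  strongly tapered or lysed cells violate the spherocylinder model and
  are better read from the projected area.
* Box-counting D on small or thin objects mixes the 1-D and 2-D
  regimes across the default size range; inspect `fit_r2` and the
  per-size counts rather than trusting a single slope.
* GLCM descriptors depend on the quantisation depth and offsets;
  values are comparable only within one configuration (which is why
  every output records its configuration sidecar).
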