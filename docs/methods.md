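# Methods

This note documents the models and procedures implemented in `fetalhc`,
the parameter choices that matter, and what the synthetic experiments do
and do not demonstrate.

## The estimation problem

Head circumference is defined as the perimeter of the ellipse a
sonographer fits to the fetal skull on a trans-thalamic ultrasound
plane, in millimetres. Two estimation routes are implemented:

1. **Segmentation route**: image → head-region probability map →
   binarization → contour detection → largest connected component →
   ellipse fit → perimeter → mm conversion.
2. **Regression route**: image → scalar network output → denormalization
   to mm. No intermediate mask exists, so this route trades
   interpretability for simplicity.

## Geometry

**Conventions.** Image coordinates have x right (columns), y down
(rows), pixel centers at integer coordinates, 0-based. Ellipse
orientation `theta` is the major-axis angle from +x in degrees,
normalized to [0, 180); constructors canonicalize `a ≥ b` (swapping axes
rotates theta by 90°) and report `theta = 0` for circles, where the
orientation is undefined — tests never assert theta on near-circular
ellipses.

**Perimeter.** The working formula is Ramanujan's second approximation
(see README). Its relative error is ≤ 1e-6 for axis ratios b/a ≥ 0.2 —
far below every other error source here — and the package carries an
exact reference, `exact_perimeter`, computed by adaptive quadrature of
the arc-length integral at ~1e-12 relative tolerance, so the
approximation error stays measurable rather than hidden. The phantom
generator deliberately uses the *exact* perimeter for ground truth.

**Ellipse fitting** uses the numerically stable direct least-squares
conic fit with the ellipse-specific constraint (Halir–Flusser
formulation): deterministic, closed-form, no initialization. Points are
centered and scaled before fitting; the conic is transformed back
exactly. Failure causes are distinguished (fewer than 5 points,
collinear/rank-deficient configurations, non-elliptical conic) because
the segmentation route treats them as recoverable per-image failures.
Noiseless round trips recover parameters to 1e-6; scikit-image's
independent ellipse model serves as a cross-check in tests, never as the
implementation.

**Anisotropic spacing and resizing.** An ellipse fitted on a resized
grid is mapped back through the exact diagonal transform of its implicit
conic (`rescale_ellipse`), not by averaging scale factors: the image of
an ellipse under an axis-aligned stretch is again an ellipse, generally
with different orientation. The same transform converts pixel-domain
ellipses to physical mm under anisotropic pixel spacing before the
perimeter formula is applied.

## Post-processing

Cleanup of a raw probability map is minimal and frozen for
reproducibility: binarize at 0.5 (`≥` keeps exact-threshold pixels),
Canny on the 0–255-scaled mask with hysteresis thresholds (100, 200)
(on a binary input any mid-range pair is equivalent), keep the largest
8-connected edge component (ties broken by the earliest pixel in
row-major order), and extract coordinates. Interior hole edges form
separate, smaller components, so holes need no explicit filling.

One numerical subtlety: Canny's non-maximum suppression quantizes edge
positions to the pixel grid, and at strongly curved, diagonally oriented
contour tips this bias is one-sided — on a 20 × 10 px ellipse at 37° the
fitted semi-major axis came out 3% short, entirely from the edge points
(a geometric-distance refit of the same points reproduced the bias).
`postprocess_to_points` therefore localizes edges on a 2× nearest-
replicated copy of the mask and maps coordinates back (fine pixel `f`
covers original coordinate `f/2 − 1/4`, exactly). This halves the NMS
quantization and brings worst-case HC recovery error on clean rasterized
ellipses (a ∈ [20, 90] px, b/a ∈ [0.5, 1]) from 2.3% to 0.66%, within
the 1% budget used by the oracle-recovery tests.

## Metrics

Dice is computed on filled regions; Hausdorff and ASSD on contour point
sets (a reported Dice of ~98–99% between thin contour *bands* would be
implausible, while "distance between two contours" only makes sense on
contours). Coordinates are scaled per-axis by the pixel spacing before
distances. PMAE averages the per-case percentage error, weighting each
image equally regardless of head size. Brute-force all-pairs distance
computations serve as test oracles for the KD-tree implementations.

## Agreement analysis

Bland–Altman uses differences predicted − reference (negative bias =
underestimation), limits bias ± 1.96·SD with the sample (n−1) standard
deviation, and counts points strictly outside the limits. Linear
agreement is OLS of predictions on reference values with r² the squared
Pearson correlation. The paired two-sided t-test compares per-image
absolute errors of two methods; degenerate cases are fixed by
convention: all-zero differences → p = 1, constant nonzero differences
→ p = 0. A Monte-Carlo null calibration (10,000 replicates, n = 30)
verifies the empirical type-I error at α = 0.05 lands in [0.03, 0.07].

## Models and training

Both networks are miniature NumPy implementations with hand-derived
gradients (verified against finite differences in the tests) and Adam:

* **TinySegNet** — encoder–decoder with skip connections; per level one
  3×3 conv + ReLU, 2×2 max pool down / nearest-neighbour upsample +
  channel concatenation up, 1×1 conv + sigmoid head. Depth 3, base 8
  filters at 64×64 input by default (~42k parameters). Trained with
  soft-Dice loss, smoothing constant 1, sums over the whole batch.
* **TinyRegNet** — three conv+ReLU+pool blocks, a top conv, global
  average pooling, inverted dropout, and a single linear output.
  Targets are HC divided by the maximum *training* HC, so predictions
  denormalize exactly and the normalization constant can never leak
  from validation or test data.

The reference training protocol (Adam, learning rate 1e-4, batch 16) is
the `TrainConfig` default; desk-scale experiments use learning rate
3e-3 and dropout keep 0.8, chosen once in an initial calibration run —
with a few thousand parameters and a few hundred images, the heavy
regularization and conservative learning rate appropriate to
ImageNet-scale backbones are counterproductive. Dropout is expressed as
the *kept* fraction throughout to avoid the rate-vs-keep ambiguity.
Epoch defaults are desk-scale (12–30 depending on task). Training is
bit-deterministic given a seed: identical seeds produce identical loss
traces.

Input images are z-scored per image (dataset-level statistics would be
an alternative; per-image keeps single-image inference stateless) and
resized to the network input. Segmentation-route predictions map the
fitted ellipse back to the native grid through the exact diagonal
transform plus the half-pixel alignment offset of the resize; the
offset moves only the center, which the perimeter does not depend on.
Unusable segmentations (blank or fragmented maps with < 5 contour
points) become logged, excluded-from-aggregates failed predictions, not
crashes.

The two routes are exposed as scikit-learn-style estimators
(`SegmentationHC`, `RegressionHC`) with `fit`/`predict`,
`get_params`/`set_params`, and trailing-underscore fitted attributes,
so they compose with sklearn model selection; the module-level
functions (`estimate_hc_segmentation`, `train`, the losses) remain the
low-level surface.

## Phantom generator

Each phantom renders: a bright elliptical skull band (thickness 8% of
the semi-major axis, ≥ 2 px) with 0–2 angular gaps removing 15% of the
band by default (real skulls have fuzzy or missing contour segments); a
darker brain-tissue interior (0.35) distinct from the background (0.15),
as parenchyma and amniotic fluid differ in echogenicity; Gaussian
background clutter blobs; a σ = 1 px point-spread blur; and
multiplicative gamma speckle (4 looks). Geometry is uniform: semi-major
axis 20–90 px in a 256² frame, axis ratio 0.6–1.0, orientation 0–180°,
center jittered ±8% of the frame.

Ground truth is exact by construction: the filled mask rasterizes the
ellipse by pixel-center membership, and the reference HC is the exact
elliptic-integral perimeter of the physical ellipse. Corruptions (gaps,
speckle, clutter) touch only the rendered image, never the ground
truth.

**Pixel spacing** is sampled per image within 0.05–0.3 mm/px, *coupled*
to the rendered perimeter: `s = 0.12 · (P_px / 250)^0.5 · ε` with
lognormal jitter (σ = 0.08), mimicking the depth/zoom behaviour of real
acquisitions (larger heads are imaged deeper, hence with coarser
pixels). This coupling is what makes physical HC learnable from the
image alone; were spacing independent of the geometry, HC in mm would
be the product of an observable (pixel perimeter) and an unobservable
(spacing), and no regressor could beat the spacing spread. An
independent-uniform mode remains available (`spacing_mode="uniform"`)
for experiments that only exercise the segmentation route, which reads
spacing from the annotation table and is immune to the coupling.

Augmentation emits, per training record, the original, a horizontal
flip (cx → W−1−cx, theta → 180−theta), and a single +10° rotation about
the frame center. Rotated masks are re-rendered from the exactly
transformed ellipse parameters; only the intensity image is
interpolated. Both operations preserve HC exactly. K-fold splits use
shuffled deterministic folds with larger test folds first (999 images,
5 folds → 200, 200, 200, 200, 199), shared across both routes.

## What the synthetic experiments show — and what they cannot

Passing tests demonstrate that the geometric chain is exact to
rasterization limits, that the metrics and agreement statistics are
correct against independent oracles, that the training loop learns, and
that under identical protocols the segmentation route estimates HC more
accurately than the regression route on these phantoms — the same
ordering reported on clinical data at full scale. The phantoms do *not*
reproduce ultrasound physics (no beam geometry, shadowing, refraction,
or anatomy beyond the skull ellipse), the miniature networks are not
competitive with ImageNet-pretrained backbones, and absolute error
magnitudes on phantoms say nothing quantitative about clinical error;
HC values also sit below the clinical 60–350 mm range because pixel
ellipse sizes and spacings are desk-scale. Problem sizes throughout
(60–999 phantoms, 64×64 network inputs, 12–30 epochs, 2-fold default
cross-validation) are the package's chosen desk-scale study conditions.

## Degenerate inputs and tie-breaks

* Empty mask: `detect_edges` returns an empty edge map;
  `largest_component` raises; the route records a failed prediction.
* Component-size ties: earliest pixel in row-major order wins.
* Circles: theta reported as 0, never asserted in comparisons.
* Both masks empty: Dice defined as 1.
* Zero-variance differences in the paired t-test: p = 1 if the mean is
  also zero, else p = 0.
* Binarization keeps pixels exactly at threshold (`≥`).
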