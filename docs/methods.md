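# Methods

## Problem and approach

In a managed tomato greenhouse the *growing truss* — the young stem tip with
its leaves — is kept nearest the camera line by the grower's line works,
roughly 0.4–0.9 m from the lens, while the canopy behind it sits 1.5 m or
farther away. A depth camera's colorized range image therefore shows the
truss as the red object on a green-to-blue background, and a short chain of
classical operations (color gating, Otsu binarization, morphology) extracts
it. Depth cameras, however, lose focus at close range, leaving contiguous
holes in the range image. The package's answer is to learn an unpaired
image-to-image translation (a CycleGAN) from plain RGB frames to
depth-colormap-style images: the translated frame feeds the *identical*
extraction chain, and is immune to the sensor's failure mode because it
never consults the sensor.

The package has four working parts: a synthetic paired-scene generator, the
translation model, the segmentation chain, and pixel-level evaluation, tied
together by an experiment driver and a CLI.

## Synthetic scenes

`SceneConfig` defaults define the emulated regime: 512×512 frames, one
truss per frame, truss depth in 0.4–0.9 m, background in 1.5–4.0 m,
clutter covering ~35 % of the background, and a 10 % per-frame chance of a
depth-camera defocus failure (the close-range failure rate reported for
this class of camera in the field). Trusses are Bézier stems with branch
offshoots and overlapping elliptical leaf blobs, proportioned like a real
truss at this working distance (a ~1 cm stem and several-cm leaves at
~1000 px/m); silhouettes are closed and hole-filled because the reference
ground truth they stand in for is a manually traced polygon. Truss color is
unsaturated plant green, deliberately invisible to the red gate, so the raw
RGB frame is a meaningful baseline. Depth colormaps are rendered through an
explicit 256-entry red→yellow→green→cyan→blue table over the fixed range
0.4–4.0 m (a fixed-range colorizer is assumed; dynamic-range presets would
change the gate's meaning frame to frame). The table is injective, so
rendering is invertible to one table step — a property the tests exploit.

A defocus failure invalidates a contiguous elliptical region of the range
image and corrupts the sensor's readings there (ground-truth geometry is
untouched: the *measurement* fails, not the plant); invalid pixels render
black, as real colorizers display holes.

What the generator does **not** emulate: photorealistic texture,
illumination spectra, camera intrinsics, occlusion between truss and
foreground hardware, and annotation error in the ground truth. Passing
tests therefore demonstrate the pipeline's internal consistency on the
geometry it was designed for, not field accuracy on greenhouse imagery.

## Translation model

Generators follow the residual translation architecture: a 7×7 convolution
then two stride-2 convolutions (encoder), eight residual blocks
(transformer), two transposed convolutions and a 7×7 output convolution
(decoder), instance normalization and ReLU after each hidden layer. The
output layer uses tanh rather than ReLU — a one-sided rectifier cannot
span the full color range — with images scaled to [−1, 1]. Discriminators
are 70×70-receptive-field patch classifiers, the standard companion to
this generator family. Losses are least-squares adversarial plus cycle
consistency (mean absolute deviation of both round trips) weighted
λ = 10; an identity term is available behind `identity_weight` but off by
default. Optimization is Adam (lr 2·10⁻⁴, β₁ 0.5) with independent
unpaired batch sampling per iteration. No image-replay pool is used; at
the scales run here the plain alternating update is stable.

The full-scale configuration (512 px, 64 base channels, 9600 iterations
at batch size 5) is expressed by the defaults but is not what the bundled
experiments run: the
networks are plain numpy, so the package's own study scale is 64 px, 8
base channels, 4 residual blocks, batch 5, 300 iterations (~20 unpaired
images per domain). At that scale training converges in minutes on one
CPU, the cycle loss falls by half or more, and the translated frames —
though far from photorealistic — are red where the truss is, which is all
the downstream gate needs. All layers carry explicit backward passes
checked against central finite differences at float64.

Determinism: every random draw (weight init, batch sampling, scenes)
derives from explicit integer seeds; two runs of the same config produce
identical loss histories and checkpoints under single-threaded BLAS (and
in practice under the same multi-thread configuration). Training aborts
with the iteration index on a non-finite loss.

## Segmentation chain

HSV gating uses the uint8 convention (H 0–179, S/V 0–255) the gate
ranges are written in; presets `a` (H 0–65, S 150–255, V 150–255), `b`
(H 0–30, S 180–245, V 250–255) and `c` (H 0–30, S 248–255, V 240–255)
are shipped as-is, including `b`'s oddly narrow bands — on clean
colormaps its S ceiling of 245 excludes fully saturated table colors
entirely, which is consistent with its rejection during development.
Preset `c` accepts table indices 0–63 (camera distance up to ~1.29 m under
the default colorizer range), i.e. exactly the near band plus the gap.

Otsu binarization is applied to the luma of the gated image (gated-out
pixels contribute zeros; luma is the natural scalarization of the gated
color image). The threshold maximizes
between-class variance over all 256 levels; ties break to the lowest
level, and a constant image maps to all-background. The foreground rule is
`gray > t`; on a perfectly bimodal image {50, 200} the argmax plateau
starts at 50, so the returned level is the plateau's low edge and the
split is still exact.

Cleanup: closing with a 5×5 elliptical footprint (it must exceed the
fixed 3×3 erosion for the stage to net-fill fragments), filling of
external contours (`binary_fill_holes`, equivalent to filling each
component's outer contour), one 3×3 erosion, then removal of 8-connected
components under 25 px. The single erosion is the pipeline's accuracy
ceiling on
thin structures: it shaves a 1-px rim, which is why clean-scene mIoU sits
near 95 % rather than 100 %, and why it degrades at 64 px working
resolution.

## Evaluation

FN% = 100·|truth∖pred|/|truth| and FP% = 100·|pred∖truth|/|pred| — the
residual-ratio convention of removing one mask from the other and
counting what remains. Each removal is normalized by the mask it happens
in: FN by the actual ROI, FP by the predicted one. mIoU is the usual
overlap/union percentage. A metric with an empty denominator is undefined
for that image and excluded (never imputed); aggregates are mean ± sample
(n−1) standard deviation, with a single-image SD reported as 0 and
flagged. ROC sweeps the gated luma (the
exact quantity the pipeline thresholds) and AUC is trapezoidal, equal to
the Mann–Whitney U-statistic with ties at ½.

## Numerical and design choices

- Color table stored explicitly (256 uint8 entries) so tests can do exact
  lookups; nearest-entry decoding defines its inverse.
- Resizing (e.g. 1600×900 → 512×512) is plain bilinear without
  letterboxing, accepting the aspect distortion.
- 16-bit depth PNGs store millimeters; 0 marks invalid pixels.
- The acceptance script's problem sizes (20 scenes at 512 px for the
  depth path; 20 training + 6 held-out scenes at 64 px, 300 iterations,
  for the translation path) are the package's study scale, chosen so a
  single CPU completes the whole protocol in minutes.

## Known limitations

- The method presumes a fixed camera-to-crop geometry; the gate's depth
  meaning breaks where working distance varies (an explicit non-goal).
- The numpy training loop is minutes-per-hundred-iterations at 64 px;
  full-scale 512-px training is expressible but impractical without a GPU
  framework.
- Translation quality at the bundled scale is sufficient for gating, not
  for photorealism; the depth→RGB generator F exists only to close the
  cycle and is not evaluated.
- Multi-frame registration/stitching of scanned sequences is out of scope;
  `scan_sequence` treats frames independently.
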