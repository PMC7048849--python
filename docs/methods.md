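# Methods

This note records the models the package implements, the choices made where
the design was genuinely open, and what the synthetic test bed does and does
not establish.

## Translation model

The translator minimizes `L_cGAN(G, D) + λ·L_L1(G)` with λ = 100 by
alternating one discriminator step and one generator step per training
sample (Adam, lr 2·10⁻⁴, β₁ = 0.5, batch size 1).  Choices this loss
formulation leaves open, and how they were resolved:

- **Generator adversarial term.**  The objective is written in its
  min–max form; for the generator update the non-saturating form
  −log D(x, G(x, z)) is used (the form that actually trains), with a
  `saturating` switch restoring +log(1 − D).
- **Decoder activation.**  The decoder description conflates "unleaky ReLU"
  with a 0.2 slope; plain ReLU is used, matching the conditional
  image-to-image convention the architecture follows.
- **Decoder widths.**  The decoder filter list
  (512, 1024, 1024, 1024, 1024, 512, 256, 128) equals the *input* widths of
  the eight deconvolution stages of a U-Net that mirrors the encoder list
  and concatenates skip connections; `GeneratorSpec` validates this identity
  and the builder derives the graph from the encoder list alone.
- **Noise.**  z is dropout (rate 0.5) in the first decoder stages, active at
  inference by default with a flag to disable.  The full net noises 3 of its
  8 decoder stages; the scaled net noises a proportional share (1 of 4).
- **Numerical guards.**  Discriminator scores are clamped to
  [1e-7, 1 − 1e-7] inside logarithms; training aborts on a non-finite loss.
- **Normalization.**  Batch normalization throughout; at batch size 1 it is
  per-instance, which the method embraces.  The generator always uses
  instance (batch) statistics, including at inference.
- **Discriminator strides.**  Four 4×4 stages at strides (2, 2, 2, 1) plus a
  stride-1 head — the unique standard four-stage completion that
  realizes a 70×70 receptive field, verified analytically and by a
  gradient-support probe.
- **Scaled architecture.**  Tests and desk-scale runs use a depth-4 U-Net
  with filters divided by 8 (and a discriminator with filters divided by 8,
  receptive field unchanged); the full-size network remains the default.
- **Initialization.**  Translator weights ~ N(0, 0.02) (the DCGAN
  convention).  The segmenter uses He-scaled encoder weights,
  zero-initialized skip-score layers and bilinear-kernel upsampling — the
  classic fully-convolutional initialization — standing in for staged
  pretrained initialization, which this package deliberately does not
  download.

All networks run on an in-package NumPy reverse-mode autodiff core
(`imtkit.nn`): im2col convolutions, transposed convolutions, batch
normalization, pooling, dropout and the loss reductions, each verified
against central-difference gradients.  Training is reproducible given a
seed in single-threaded mode (the test suite pins BLAS and SimpleITK to one
thread; reduction order changes with thread count).

## Preprocessing

Volumes are sliced along z, resized to a square side (bilinear for
intensities, nearest-neighbor for labels), min–max scaled to [0, 1] and
mapped by v → (v − 0.5)/0.5 into [−1, 1].  Scaling is per-slice (robust to
slice-wise drift; a per-volume variant would be a one-line change at the
call site since normalization acts on slices).  A constant slice has no
range: it maps to all zeros (mid-gray) with a warning rather than erroring,
so background-only slices survive batch pipelines.  Tumor sub-labels
(necrosis, edema, non-enhancing, enhancing — indices 1–4 by default) merge
into one tumor class; unknown indices raise, naming the index.  Small
fields of view are first cropped to the tight foreground bounding box and
resized to a cube.  Coordinates are 0-based, (row, col) = (y, x), z =
depth; landmarks are stored in voxel units as (x, y, z).

## Synthetic phantom

Each subject is one anatomy — a gray-matter ellipse, a white-matter ellipse
strictly inside it, two CSF ventricles inside the white matter, optionally
a tumor blob painted only over wm/gm — jittered per seed.  A modality is a
per-tissue mean map (means pairwise ≥ 0.05 apart) times a unit-mean
multiplicative bias field (Gaussian-blurred white noise, blur σ = side/8,
amplitude default 0.05 — emulating acquisition inhomogeneity) plus additive
Gaussian noise, clipped to [0, 1] and mapped to [−1, 1].  Seven landmarks
mirror the ventricle scheme: superior/inferior/lateral extrema of each
ventricle plus the csf pixel nearest the csf centroid ("middle").  All
randomness flows through explicit seeds; a cohort serializes
byte-identically given its seed.

Scenario presets, chosen once as the study conditions:

- `linear_contrast_profiles` — modality B's tissue means are an affine map
  of A's (slope 0.6, intercept 0.2; B noiseless).  Supports parameter
  recovery: a translator trained A→B should regress on the noiseless target
  with slope ≈ 1.
- `low_contrast_profiles` — the given modality's wm/gm boundary gap (0.06)
  equals its noise sd, so boundary contrast sits at the noise floor, while
  the second modality separates wm/gm by 0.40.  The registration-fusion
  scenario.
- `faint_tumor_profiles` — tumor is 0.06 above white matter against noise
  sd 0.04 in the given modality but bright (0.95 vs 0.35) in the target.
  The multichannel-segmentation scenario.

What the phantom does **not** emulate: MR physics (no Bloch equations or
k-space artifacts), partial-volume mixing, skull/CSF periphery, or real
anatomical variability.  Passing tests show the algorithms exploit
cross-modality information under controlled contrast/noise conditions; they
do not certify performance on clinical MRI.

## Registration

The builtin backend registers 2-D slices by (1) center-of-mass plus
exhaustive-rotation rigid initialization (coarse 3° grid over ±45°, 1°
refinement, scored by normalized cross-correlation at quarter resolution),
then (2) symmetric-forces demons (SimpleITK) over a 3-level pyramid
(shrink 4/2/1, 60/40/20 iterations, Gaussian field smoothing sd 1.5) on
histogram-matched intensities.  If similarity worsens on two consecutive
levels the best field so far is returned with a warning.  The rigid and
demons maps compose analytically into one displacement field on the fixed
grid.  An adapter seam (`register_backend`, `CommandTemplateBackend`)
admits external tools; the package does not reimplement or ship them.

Fusion is a pointwise convex combination of displacement fields,
φ = w·φ_translated + (1 − w)·φ_given — the simplest operator consistent
with scalar fusion weights; the weight attaches to the translated-modality
field and is selected by cross-validated grid search over
{0, 0.05, …, 1} maximizing the target-structure Dice.  Fields are fused
before label warping.  Label propagation averages the n one-hot warped
atlas labels; the final label is the per-pixel argmax with ties to the
lowest class index.  Landmark error is the mean 3-D Euclidean distance
after stacking slices.  The registration application consumes the
translator's deterministic output (inference dropout disabled).

## Segmentation (TMS)

Channel stacks are (given, given, translated), or (given, given, given) as
the baseline, feeding a three-pool fully convolutional segmenter whose
final stream fuses score maps from the last two pooling stages before
upsampling to full resolution.  Training is SGD with the classic recipe
(lr 10⁻⁴, momentum 0.99, weight decay 5·10⁻⁴) on the *summed* per-pixel
cross-entropy — the unnormalized loss this recipe was designed for — with
two stabilizers required by random initialization: global gradient-norm
clipping at 1.0, and returning the snapshot from the epoch with the lowest
mean training loss (heavy momentum makes the terminal epoch a lottery).
Class imbalance is handled by unweighted cross-entropy by default; the
tumor experiments enable the inverse-frequency flag because tumor occupies
~2% of pixels.  Δ is reported as a relative percent increment,
(TMS − baseline)/baseline.

## Problem sizes

The shipped experiments run at phantom scale, chosen as the package's own
test-bed sizes: translation training cohorts of 20 subjects (100 for the
faint-tumor translator, which must generalize a subtle amplification rule),
sides 64–128, 30–250 epochs; registration cohorts of 1 fixed + 4 atlas
subjects at side 128 across 10 seeds; segmentation with 12 training and 8
test subjects per run across 10 seeds.  Directional claims (fusion benefit,
TMS benefit) are asserted as win counts across seeds against their
real-modality upper bounds, not as absolute Dice levels.

## Known limitations

- 2-D only, matching the slice-based pipeline; volumes are handled
  slice-wise and restacked.
- The NumPy core is CPU-bound; the full 256×256 eight-level architecture
  trains only at real-data scale budgets, not in the test suite.
- Global (whole-image) SSIM is the primary definition here; the windowed
  variant exists behind a flag for comparability with common libraries.
- Mutual information is reported in nats with 64 histogram bins; the
  log base and binning are declared rather than standardized.
- PSNR's MAX follows the literal "maximum pixel value of the two images"
  (pair-max); a dynamic-range mode is available since the literal reading
  is nonstandard.
- Empty-vs-empty Dice is defined as 1.0 (absence correctly predicted).
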