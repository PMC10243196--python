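# Methods

## Problem and system overview

Field robots that segment crops from weeds (to target herbicide, count
plants, or monitor growth) work from camera frames that are frequently
degraded by motion blur — vehicle vibration, camera shake, wind-moved
foliage.  Blur erases exactly the fine leaf boundaries a semantic
segmentation network needs, so accuracy collapses on blurred frames.
This package implements a two-stage remedy: a restoration network
deblurs the frame, then a standard U-Net assigns each pixel to
background, crop, or weed.  The stages are trained in sequence — the
restorer on blurred/sharp pairs, then, with the restorer frozen, the
segmenter on restored images — so the segmenter learns the statistics
of the images it will actually see in deployment.

## The restoration model

The deblurring network (`MotionDeblurNet`) is an encoder/decoder CNN
that predicts a residual correction `F_res` to its input and emits

    I_restored = tanh(F_res + I_blur),

with images living in [-1, 1].  The residual form means the untrained
network is already a near-identity map and training concentrates on the
blur difference.

**Encoder.**  A two-conv stem (3 -> C -> C, instance norm + ReLU) feeds a
stack of *multi-receptive-field attention blocks*.  Each block runs four
parallel chains of depthwise-separable conv units (pointwise 1x1 then
depthwise 3x3, norm, ReLU) of depths n = 1, 2, 3, 4, so the chains see
receptive fields of (1 + 2n) = 3, 5, 7 and 9 pixels.  Their concatenated
output (4C channels) is fused back to C by a pointwise conv, passed
through a two-layer pointwise attention gate (sigmoid weights in (0,1)
multiply the features), and added to the block input through a learnable
per-channel skip scale `alpha` initialized to zero — the block starts as
a pure feature-extraction branch and learns how much of the (blurred)
input to let through.  A refining 3x3 conv emits the skip tensor passed
to the decoder; a strided 2x2 conv halves the resolution between levels.
Depthwise separability keeps the conv cost of each unit at C^2 + 9C
parameters versus 9C^2 for a standard 3x3 conv.

**Decoder.**  Each decoder level doubles the resolution with a pointwise
expansion to 4C followed by pixelshuffle, concatenates the encoder skip,
fuses with a 3x3 conv, and refines with a *deformable residual block*:
a modulated deformable 3x3 convolution (per-tap learned offsets sampled
bilinearly, per-tap multiplicative modulation) followed by ReLU and a
3x3 conv, wrapped in a residual sum.  Deformable sampling lets the
decoder gather evidence along the motion path that displaced each pixel.
The offset/modulation predictor is zero-initialized with modulation
`2*sigmoid(raw)`, so at initialization the block equals a plain conv
resblock — this both stabilizes early training and provides an exact
standard-convolution oracle for testing.

**Normalization placement.**  All encoder normalization is instance
norm, all decoder normalization is batch norm.  Restoration training
uses small patches at batch size 2, where batch statistics are noisy;
per-instance statistics are the safer choice upstream, while the
decoder's aggregation conv benefits from batch calibration.  This is
the configuration that won the normalization ablation; the test suite
asserts the placement by introspection.

**Output head.**  Three 3x3 convs taper C -> C/2 -> C/4 -> 3.  The final
conv is zero-initialized by default, making the fresh network exactly
`tanh(input)`; set `zero_init_output=False` to start from a small random
residual instead (we found both reach the same optimum under Adam; the
zero start is kept for its exact identity-at-init property).

**Defaults.**  Channel width C = 128 and three encoder levels (the depth
is configurable; spatial dims must be divisible by 2^(levels-1)).  The
full-size model has ~3.03 M parameters; `expected_parameter_count`
gives the closed-form count for any configuration and is tested against
the built model.

## Losses and metrics

Restoration training minimizes

    L = lambda1 * (1 - SSIM(I_restored, I_target)) + (1 - lambda1) * L1,

with lambda1 = 0.84.  SSIM uses the stabilizers m = 2.55 and n = 7.5
(squared inside the formula); these are calibrated to the 0-255
dynamic range (m = 0.01 * 255), so the SSIM term is evaluated after
rescaling images by (x+1)*127.5, while the L1 term stays in [-1, 1].
The loss's local statistics come from an 11x11 Gaussian window
(sigma 1.5) applied as a separable depthwise convolution over the valid
region, end-to-end differentiable in the package's own autodiff.

The *reported* SSIM metric uses the same windowed statistics (global
whole-image statistics are available for oracle tests) and matches
scikit-image's implementation to machine precision once the stabilizers
are translated into its K1/K2 parametrization.  PSNR is
10*log10(255^2 / MSE) with the MSE averaged over all pixels and
channels and Max interpreted as the 8-bit dynamic range (identical
images report +inf).

Segmentation training minimizes the Dice loss, one minus the mean
per-class Dice overlap between the softmax probability map and one-hot
labels, with epsilon = 1e-6 guarding empty classes.  Reported
segmentation quality uses per-class IOU = TP/(TP+FP+FN), their
unweighted mean (mIOU, background included), macro Recall and
Precision, and the F1 of the macro means.  A class absent from both
prediction and ground truth scores 1.0 (vacuous truth) rather than NaN;
the event is logged.

## Synthetic data

Nothing in the build depends on external datasets; `deblurseg.synth`
manufactures both halves of the supervision.

**Blur.**  Camera shake is modeled as a random trajectory with momentum:
velocity v_{t+1} = inertia * v_t + Gaussian impulse, positions are the
cumulative sums recentred on the origin (defaults: 64 steps, inertia
0.7, unit impulses, 33x33 kernel canvas).  The trajectory is auto-
rescaled (never clipped, so no mass is lost) to fit the canvas and
splatted with bilinear weights into a unit-sum point-spread function.
Blurring convolves each channel with reflect padding, which preserves
constant images exactly and never increases image variance — both are
asserted as properties.

**Scenes.**  A scene is soil-textured background (smoothed Gaussian
noise around a soil tone) with crop plants (rosettes of 4-6 overlapping
green ellipses) and smaller, hue-shifted weed blobs.  Labels are painted
together with the pixels, so the label map is exact by construction, and
plants are placed with a minimum separation so connected components per
class equal the requested counts.  The default palette models diffuse
daylight: tones stay in the middle of the 8-bit range (roughly [-0.55,
0.45] after normalization), where the model's output tanh is close to
linear.  What the generator does *not* model: perspective, leaf texture,
specular highlights, shadows, sensor noise, class imbalance beyond
plant/soil area, or blur that varies across the frame.  Passing tests
therefore demonstrate that the machinery works end to end at small
scale, not field-ready accuracy.

## Training procedure

Stage 1 fits the restorer with Adam (betas 0.9/0.999) on random aligned
crops of the blurred/sharp pairs; the learning rate follows cosine
annealing from 1e-4 to 1e-7 over the whole run (per optimizer step, no
restarts).  Full-scale defaults: 256x256 patches, batch 2, 450 epochs.
Stage 2 freezes the restorer — restored inputs are produced by
inference only, so no gradient can reach it, and the test suite asserts
its state dict is bit-identical before and after — and fits the U-Net
with Adam at 1e-5 on the chosen input regime.  Validation uses a
deterministic seeded 10% split.  Every run is reproducible from its
seed (init, batch order, crop positions).

The five-scheme ablation harness trains and evaluates the segmenter
under (train-input, test-input) combinations — (sharp, sharp), (sharp,
blurred), (blurred, blurred), (sharp, restored), (restored, restored) —
to quantify how much of the accuracy lost to blur the restorer recovers.

## Scaled-down study conditions

The package is developed and tested on one CPU, so the learning
experiments run a miniature version of the full recipe.  These
conditions were fixed once, after a feasibility analysis, and the
acceptance tests simply run them:

* restoration study: 96x96 scenes (2 crops, 3 weeds, radii 7-11 / 3-5
  px), 8 training pairs, 6 held-out pairs, 11x11 blur kernel with
  trajectory inertia 0.3; restorer C = 8, levels = 2, trained 200 steps
  on 64x64 random crops, batch 4, cosine 2e-3 -> 2e-5.  Held-out quality
  is measured through the package's own patch-based inference (64-px
  tiles, stride 32), matching the patch statistics the network was
  trained on.
* scheme ablation: finer plant structure (2 crops radii 6-9, 6 weeds
  radii 2-4) and a stronger 13x13 kernel, so the mIOU damage from blur
  is boundary-dominated and large (~0.2) relative to replicate noise;
  the harness restorer gets a longer 500-step fit (the 200-step model is
  too marginal for its restorations to help reliably), and the mean
  ordering is taken over five replicate seeds of fresh scenes and
  segmenter fits.  Segmenter: U-Net base width 8, 300 steps, Adam 1e-3
  (the full-scale 1e-5 moves the Dice loss negligibly in so few steps,
  and shorter fits are still in their optimizer transient, so a
  replicate would measure training luck rather than the data regime).

The feasibility analysis deserves a note: with full-frame 64x64 training
patches the tiny network memorizes the eight training scenes (training
PSNR improves while held-out PSNR drops), so the tiny experiments crop
64x64 patches from larger 96x96 frames — the same crop-from-frame
regime as the full recipe.  Blur strength was chosen so that an optimal
linear deconvolution filter fit on the training pairs generalizes with a
clearly positive held-out PSNR gain, i.e. the task is solvable in
principle at this scale; the tiny network recovers a fraction of that
ceiling in its 200 steps.  Typical results: held-out PSNR gain of order
+0.01 to +0.1 dB over the blurred baseline after 200 steps, and a
scheme-ablation mean-mIOU ordering sharp > restored > blurred.  Both
effects are real but small at this scale, and single replicates of the
ablation can invert the restored/blurred ordering — the claim is about
means over replicates.

## Numerical choices

* All arithmetic is float64; the conv/deform/pooling backward passes are
  verified against central finite differences at tolerance 1e-6 (1e-5
  for deformable sampling).
* Instance norm uses eps = 1e-5 and no running statistics; batch norm
  tracks running statistics with momentum 0.1 and uses them in eval
  mode.
* Deformable sampling outside the image reads zeros, matching the zero
  padding of the standard conv it reduces to at zero offsets.
* Tile stitching averages overlapping predictions with uniform weights
  in float64; with the default stride = patch/2 the per-pixel coverage
  counts are powers of two and stitching crops of one image reproduces
  it bit-exactly.
* Label argmax ties break toward the lowest class index.
* PSNR of identical images returns +inf rather than raising.

## Design shape

Training is exposed statsmodels-style: `RestorationTrainer(...).fit(pairs)`
returns a result object holding the fitted model, the per-epoch history
and a `summary()` table.  A full estimator/results split (standard
errors, inference on parameters) does not map onto CNN fitting, so the
rest of the package keeps a functional surface.

## Known limitations

* The synthetic scenes are far easier than real field imagery; numbers
  here say nothing quantitative about CWFID-class datasets.
* Spatially uniform blur only (one kernel per frame).
* The NumPy backend is single-threaded BLAS-bound; full-scale (C = 128,
  450 epochs) training is out of its reach by design — the package
  targets correctness and testability, not throughput.
* No data augmentation beyond random crops, mirroring the recipe it
  implements.
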