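# Methods

This note documents the models, protocols and numerical choices behind the
package, in the order data flows through it.

## The weakly supervised U-Net and its comparator

**WSUnet.** A standard U-Net with `depth = 4` down/up-sampling levels and
`base_filters = 8` channels at the first level, doubling per level to a
128-channel bottleneck.  Every block applies two 3×3 convolutions, each
followed by batch normalisation and rectified-linear activation, and one
spatial-dropout layer (rate 0.1) after the second activation.  Upsampling
uses 2×2 transposed convolutions with stride 2; each decoder level
concatenates the matching encoder feature grid.  A 1×1 convolution with
sigmoid activation produces the full-resolution voxel-probability map, and
a global max-pooling layer reduces it to the image-level probability.  At
128×128×1 input this is 487,145 trainable parameters (batch-norm scale and
shift included, running statistics excluded); parameter budgets are quoted
in thousands truncated toward zero (487 k).

**sCNN.** The comparator shares the WSUnet contracting path including the
bottleneck, then flattens the 8×8×128 grid into a dense layer of width 128
(relu) and a single sigmoid unit: 1,344,729 parameters (1344 k).  Counting
convolutional layers in forward order (transposed convolutions included),
its 7th and 9th convolutional layers produce (16,16,64) and (8,8,128)
feature grids — the two Grad-CAM tap points.

**Initialisation.** Glorot-uniform weights from a seeded generator; builds
are bit-reproducible given (config, seed).  The voxel-logit bias starts at
−2 (a detection-prior initialisation): positive voxels are rare, and with a
zero bias the maximum over ~16 k near-symmetric sigmoid outputs saturates
the initial image probability, starving early training of gradient.  The
prior does not change parameter counts.

**Why a bespoke numpy backend.** The architectures, training loop and
attribution methods run on a small reverse-mode autodiff engine
(`wsunet.nn`) written for this package: convolutions are im2col + BLAS
matmul, gradients are verified against central finite differences in the
test suite, and everything is deterministic on a single thread.  Inference
runs in a no-grad mode so that large batches do not retain backward
buffers.

## Training protocol

Image-level binary cross-entropy (computed in stable logit form on the
max-pooled voxel logit) minimised with Adam at learning rate 0.001
(β₁ = 0.9, β₂ = 0.999, ε = 1e−7).  Voxel masks are structurally withheld
from the optimiser — the training loop discards them on entry — and are
used only to compute the per-epoch validation trace of voxel precision,
recall, dice and AUPR, which documents how voxel-level behaviour drifts
while image-level loss is flat.

- **Augmentation:** independent horizontal flip (p = 0.5), vertical flip
  (p = 0.5) and a rotation drawn uniformly from {0°, 90°, 180°, 270°},
  re-sampled every epoch; masks follow the identical transform.
- **Early stopping:** training stops when validation loss has not improved
  by more than `min_delta = 1e−4` for `patience = 5` consecutive epochs;
  the best-validation weights are restored.  Both the min-delta guard and
  best-weight restoration are this package's choices where the protocol is
  otherwise silent.
- **Cross-validation:** subjects are shuffled by seed and dealt round-robin
  into 5 patient-disjoint folds (all patches of a subject share a fold);
  fold k trains on the rest and validates on fold k.
- **Batch size 32** by default (8 in the scaled study below — more
  optimiser steps per epoch at small dataset sizes).
- **Batch-norm momentum 0.9** for the running statistics: desk-scale runs
  take a few hundred optimiser steps, and a slower constant leaves the
  inference-mode statistics far from the batch statistics.

## Patch-sampling protocol

Volumes arrive in Hounsfield units (DICOM series are read with slice
sorting and rescale slope/intercept applied; NIfTI image/mask pairs are
read directly) and are scaled by 0.001, so water is 0.0 and air is −1.0.
Per subject, 40 axial 128×128 patches are centred on tumour voxels drawn
uniformly **with replacement** (small lesions have fewer distinct voxels
than draws), and 40 contralateral patches are centred on tumour voxels
reflected across the sagittal midplane (j → W−1−j, an exact involution)
and offset by independent uniform integer draws within ±15 voxels axially
and ±75 coronally/sagittally.  Conventions where the protocol is
underdetermined:

- the centre is the voxel at (H/2, W/2) of a half-open [c−64, c+64) window;
- centres are clamped so the window lies fully inside the volume — no
  padding, which could leak label information;
- every patch is labelled by the single stated rule — positive iff the
  window holds at least one tumour voxel.  Contralateral patches that
  happen to contain tumour are kept and relabelled positive, not discarded.

## Attribution methods

- **Grad-CAM** at a chosen convolutional layer: channel weights are spatial
  means of ∂(image probability)/∂(activations); the map is the rectified
  channel-weighted activation sum at native resolution, upsampled to the
  input grid by nearest-neighbour interpolation (value set preserved).
- **Integrated gradients**: right-endpoint Riemann approximation of the
  path integral from an all-zero baseline (≈ water after scaling),
  attribution = (x − x₀) ⊙ mean_{k=1..K} ∇f(x₀ + (k/K)(x − x₀)), K = 10 by
  default; exact for linear models at any K, complete (summing to
  f(x) − f(x₀)) as K grows.
- **Occlusion sensitivity**: a square window of width 10 filled with 0
  slides over the stride grid; each pixel receives the mean score drop
  over all windows covering it, and exactly 0 where no window reaches.
  Stride and fill value are configurable; stride 1 is the default,
  coarser strides trade resolution for speed.
- **Joint normalisation** (display only): a set of same-method maps is
  affinely rescaled to [0,1] by the min/max pooled across the set; metric
  computations always use raw values.

The WSUnet's own voxel map needs none of this machinery: its maximum *is*
the image prediction, so the explanation is causally faithful by
construction (asserted bitwise in the tests).

## Evaluation

Voxel metrics pool voxels over all patches (micro-averaging, matching a
single dataset-level number): precision, recall and dice at threshold 0.5,
AUPR by average-precision summation over the descending-score sweep, and
expected calibration error with 10 equal-width bins.  Zero-denominator
convention: a ratio is 1 when prediction and truth are both empty and 0
when the denominator vanishes while errors exist.  Saliency comparators
produce unbounded scores, so only AUPR is computed for them; calibration
and thresholded metrics are reserved for probability-valued predictions.
Image metrics are accuracy, sensitivity and specificity at 0.5 plus the
rank-based AUC (ties count one half).

Confidence intervals: 500 nonparametric bootstrap replicates of the
evaluation unit (patches by default; subjects optionally), reporting the
2.5th and 97.5th centiles.  Replicates on which a metric is undefined
(single-class resamples) are redrawn with a retry cap.

## The phantom generator

Each subject is a (32–40)×256×256-voxel grid: an elliptical soft-tissue
body (+40 HU) on air (−1000 HU), two mirror-symmetric ellipsoidal lung
fields (−800 HU), and 1–3 lesions (−50 HU) of 4–8-voxel radius placed
strictly inside **one** lung — the other lung stays lesion-free so
contralateral mirroring yields negatives.  A lesion is the union of up to
three jittered ellipsoids, morphologically closed, clipped to the lung.
Gaussian noise (σ = 20 HU) is added from an RNG stream separate from the
lesion stream, so regenerating a subject without lesions reproduces the
identical background.  Optional rib-like +700 HU arcs around the lungs act
as confounders for saliency experiments and are off by default.

What the generator does *not* emulate: reconstruction physics (beam
hardening, kernels), parenchymal and lesion texture, anatomical
variability, partial-volume boundaries, and co-occurring pathology.
Passing tests therefore demonstrate that the method and its implementation
behave as specified under clean, high-contrast conditions; they do not
predict clinical-grade performance on real CT.

## The scaled-down weak-supervision study

The central scientific check trains on phantoms at a size a CPU handles in
minutes: 60 subjects with 32×192×192 volumes, lesion radii 5–8 voxels and
σ = 10 HU noise; 4 tumour-centred + 4 contralateral 96×96 patches per
subject (offsets ±15/±50/±50); the reference depth-4/base-8 architecture;
batch size 8; at most 8 epochs with patience 5; a single patient-disjoint
validation fold (12 of 60 subjects).  Occlusion sensitivity on the
comparator uses stride 12 at this scale.  The study runs for three seeds
and claims are aggregated by the **median**, since voxel-level performance
is known to vary across initialisations at fixed image-level loss.  Under
these conditions the WSUnet's voxel AUPR sits an order of magnitude above
the positive-voxel prevalence, far above occlusion sensitivity, while its
image-level AUC matches the standard CNN's within a few hundredths.

A cautionary observation from developing these conditions: a much narrower
U-Net (base width 4) learns the *image* task equally well but concentrates
its voxel probabilities a few voxels *outside* the lesion rim —
peritumoural shortcut learning that image-level metrics cannot detect.
The phenomenon disappears at the reference width.  This is exactly the
failure mode that makes voxel-level audits of weakly supervised models
necessary, and the narrow-model behaviour is left reproducible via the
configurable architecture.

## Pipeline and reproducibility

`wsunet.pipeline.run_pipeline` executes simulate → sample → train →
explain → evaluate under one output directory with a JSON manifest of
SHA-256 checksums; a stage re-runs only when its config, seed or inputs
change or an output fails verification.  Stage seeds derive from the root
seed and the stage name.  The training stage reads only the image array
and the label manifest — the mask file is never opened, which the test
suite asserts with a file-access audit.  All randomness flows through
seeded `numpy` generators; runs are bit-reproducible on a single thread.

## Known limitations

- The engine is CPU-only and tuned for desk-scale problems; the reference
  architecture trains at ~20–40 images/s at 96×96.
- Image-level max-pool supervision is negatively biased at voxel level
  (under-segmentation by design); recall should be read accordingly.
- RTSTRUCT contour rasterisation, resampling to isotropic spacing, 3D
  patches and whole-volume deployment are out of scope.
- The bootstrap treats patches as exchangeable units by default; patches
  of one subject are correlated, so subject-level resampling is available
  where that matters.
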