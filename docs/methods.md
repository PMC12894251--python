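# Methods notes

This note records the modeling assumptions, the defaults and why they were
chosen, the numerical conventions, and what the synthetic phantom does and
does not establish about behavior on real FLAIR MRI.

## Problem setting

MS lesions appear as small, irregular hyperintense foci in FLAIR MRI.  The
package treats segmentation as per-pixel binary classification on 2D axial
slices: 3D volumes are sliced, filtered, preprocessed, and fed to a
U-shaped network whose sigmoid output is thresholded (default 0.5).

## Phantom generator

The phantom emulates the intensity structure this pipeline depends on, with
fixed reference levels so oracle checks are exact:

- background 0; brain tissue 100 inside an ellipsoid; optional skull ring at
  180, separated from the brain by a dark gap (so the skull-strip stage has
  a ring to remove); lesions at 100 × `lesion_contrast` (default 1.6);
- spherical lesions placed by rejection sampling (≤ 1000 attempts per
  lesion, error naming the first unplaceable lesion), fully inside the
  brain and pairwise separated by more than one voxel so 26-connected
  labeling recovers exactly `lesion_count` components;
- multiplicative bias field `1 + a·P₂` with a random degree-2 polynomial
  normalized to zero mean and unit peak over the brain (default amplitude
  0.2) — exactly the artifact class the polynomial bias correction removes;
- additive Gaussian noise (default σ = 4, i.e. 4 % of tissue level);
- all randomness flows from the single spec seed; identical spec + seed is
  bit-identical.

Defaults (32×128×128 voxels, 8 lesions of radius 2–5 voxels) are a
desk-scale compromise: large enough that slice filtering, skull stripping
and training all have realistic work to do, small enough to run in seconds.
They are not calibrated to any cohort's lesion-size distribution.

What the phantom does **not** model: MRI acquisition physics (no k-space,
no Rician noise), partial-volume effects, anatomical texture
(gyri/ventricles), multi-modal contrast, or longitudinal change.  Passing
tests on phantoms therefore demonstrate correctness of the algorithms and
the learning machinery, not clinical-grade accuracy on patient data.

## Preprocessing conventions

- **Orientation**: volumes are reoriented so axis 0 is the axial stacking
  axis (inferior→superior), slices indexed from 0.
- **Slice retention**: first restrict to the central band of the stack
  (default fraction 0.70, i.e. the initial and terminal ~15 % of slices are
  dropped — those mostly show peripheral brain), then keep slices whose
  mask has ≥ 5 foreground pixels.  "Lesion size" is read as total
  foreground pixels per slice; a per-connected-component reading is
  available behind `per_component=True`.  Slices remember their source
  depth, which makes the filter idempotent.
- **Skull strip**: contrast stretch → histogram equalization → Otsu →
  morphological opening then closing (disk radius 2) → largest connected
  component → hole filling; the image is multiplied by the brain mask, the
  lesion mask is never touched.  A constant slice raises
  "degenerate intensity histogram".
- **NL-means**: weights `exp(−‖patch_p − patch_q‖² / h²)` normalized per
  pixel over an 11×11 search window with 3×3 patches, patches read from a
  reflect-padded image.  Default `h` = 0.8 × a Laplacian-based noise
  estimate.  This is implemented directly (and checked against a
  brute-force double loop) because the common library variant uses a
  noise-compensated distance and would not match this definition.
- **Bias correction**: default is a degree-2 polynomial surface fitted to
  log-intensity over the brain region by least squares; the image is
  divided by the exponentiated fit renormalized to unit mean over that
  region (so an unbiased image is a fixed point).  A delegated N4 mode
  calls SimpleITK when available; `none` is the identity.
- **Resize**: bilinear for images, nearest-neighbor + re-binarization for
  masks; default target 256×256.  Per-slice min–max normalization to [0,1]
  afterwards.

## Augmentation

Rotations by 45°, 90°, 125° about the image center, scalings by 1.5 and 2
(zoom then center-crop back to the original frame; center-pad for
factors < 1), and one horizontal translation (default 10 % of width).
Images interpolate bilinearly, masks nearest-neighbor; both receive the
same geometric parameters.  One output per listed parameter plus the
original gives a 7× expansion.  Augmentation applies to training slices
only.  Not modeled (by design): flips, elastic deformation, intensity
augmentation.

## Network

Encoder widths follow VGG-16 (64, 128, 256, 512, 512; 13 conv layers); the
progressively-increasing filter list (16, 32, 64, 128, 256) belongs to the
decoder levels.  Skip taps are the last pre-pool activation of blocks 1–4;
the ASPP bottleneck runs on the block-5 post-pool output (stride 32), so
the decoder has a skip-free first stage (stride 32→16) at the deepest
decoder width before the four attention-gated skip levels.  Grayscale
inputs are replicated to three channels to match the VGG stem.

Attention is applied on the skip side (the alternative — gating the
upsampled decoder feature — is available as `attention_site="upsampled"`),
spatial gate before channel gate; with both sigmoids saturated at 1 the
block is the identity and the model reduces to a plain skip-connected
encoder–decoder.  The channel MLP hidden width is max(C/8, 1).  ASPP
branches are summed into the fusion step by channel concatenation + 1×1
convolution (not an elementwise sum).  Dropout (0.2) sits after the ASPP
fusion and after each decoder conv pair, active only in training.

Initialization: He-normal weights from the model seed, zero biases, with
two deliberate exceptions.  The final 1×1 head bias starts at −2 — a
prior-aware start that reflects how rare lesion pixels are and avoids the
initial all-background plateau of BCE training under heavy class
imbalance.  Both attention-gate biases (the spatial 7×7 conv bias and the
channel MLP output bias) start at +2, so the gates open near 1 and the
block is approximately the identity at initialization; closed gates at
init (sigmoid(0) = 0.5 twice per skip) measurably attenuate decoder
activations and gradients and slow early training.  Transfer-learned encoder weights can
be loaded from an `.npz`; nothing is downloaded.

Upsampling is bilinear ×2 followed by a 3×3 convolution (no transposed
convolutions, avoiding checkerboard artifacts).  Inputs must be divisible
by 32 (five pooling stages).

## Training

Defaults mirror the reference recipe: BCE loss (the raw per-pixel sum is
reported; the mean-reduced variant drives optimization so the learning rate
is independent of image size), Adam at 0.001, batch size 4, dropout 0.2,
100 epochs, threshold 0.5, probability clamp ε = 1e-7.  Splits are at the
patient level (ceil(n·fraction) patients to test, seeded shuffle); training
aborts if a declared test patient appears in the training slices.  The
encoder freeze lasts `freeze_epochs` epochs — default the whole run, since
unfreezing is only useful with pretrained weights; the learning-capacity
checks train with `freeze_epochs=0` because their encoder is random.

Per-epoch history records the mean batch loss and a Dice computed from the
training-batch predictions (dropout active), which slightly understates the
model; definitive numbers come from inference-mode prediction.

### Desk-scale profile

`ModelConfig.desk_scale()` keeps the exact topology (5 blocks, 13 convs,
4-rate ASPP + GAP, DHA on every skip) with encoder widths 8–64, ASPP at 32,
and decoder widths 16, 16, 32, 64, 64.  The shallow decoder levels are not
narrower than 16 channels: with fewer, some initializations leave every
channel of the final level ReLU-dead on the rare foreground pixels, pinning
the output at the head bias with no recoverable gradient.  The
learning-capacity check — 8 phantom slices at 128×128, random-init encoder,
≤ 300 Adam steps, batch 4 — reaches mean train Dice ≥ 0.9 in a few minutes
on one CPU.  This problem size was chosen so the whole suite runs at a desk;
the reference profile (256×256, 100 epochs) is retained as the default
configuration for real experiments.

## Evaluation

Confusion counts are exact pixel tallies; the panel computes the six
metrics with a zero-denominator convention of 1 when the numerator
condition is vacuous (e.g. empty ground truth and empty prediction give
Dice 1) and FPR 0 when FP+TN = 0.  Two aggregations are provided:
`per_slice_mean` (default; arithmetic mean of per-slice metrics) and
`pooled_counts` (panel of summed counts).  Note that J = D/(2−D) holds per
confusion table but **not** for averaged metrics — a mean Jaccard that
disagrees with the mean Dice under this identity is expected behavior of
per-slice averaging, not a bug.

## Grad-CAM

Classification Grad-CAM needs a scalar objective; for this dense sigmoid
output the objective is the mean pre-sigmoid logit over predicted
foreground pixels (over all pixels when the prediction is empty).  Channel
weights are spatial means of the objective's gradient at the target layer
(default: the ASPP fusion output; any captured layer may be named), the raw
map is the ReLU'd weighted activation sum, bilinearly upsampled and min–max
normalized — identically zero maps stay zero rather than dividing by zero.
The DHA spatial maps and channel gates are separately exportable from the
model for comparison.

## Numerical engine

All network math runs on float64 NumPy arrays through a small reverse-mode
autodiff engine: stride-1 same-padded (optionally dilated)
cross-correlation via im2col + BLAS, 2×2 max pooling with first-argmax
tie-breaking, matrix-based bilinear resizing, broadcasting add/mul with
gradient unbroadcasting, and a clamped BCE node.  Gradients are validated
against central finite differences (relative error ~1e-8).  Adam follows
the standard bias-corrected form.  Determinism: identical inputs, seeds and
thread configuration give bit-identical runs; there is no hidden global
random state.

## Known limitations

- CPU-only and desk-scale: the full-width profile at 256×256 trains far too
  slowly on one CPU for real experiments; the implementation is for
  correctness, inspection and small studies.
- No validation split, learning-rate schedule or early stopping beyond an
  optional target-Dice stop; none are part of the reference recipe.
- The skull-strip stage is a classical 2D pipeline, not a learned brain
  extractor; on real data it is a rough substitute for dedicated tools.
- Surface-distance metrics (HD95, ASSD) and lesion-wise detection scores
  are out of scope.
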