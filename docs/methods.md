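# Methods

## Problem and model

The package segments gliomas in multimodal 3D MRI. Each case is four
co-registered, skull-stripped contrasts (FLAIR, T1, T1-CE, T2) and the
label set is the BraTS convention: 0 background, 1 necrosis, 2 edema,
4 enhancing tumor, evaluated over the nested regions ET = {4},
TC = {1, 4}, WT = {1, 2, 4}.

The model is a V-Net-style fully convolutional encoder–decoder with two
additions:

1. **Multi-depth fusion blocks** in the encoder, one in front of each
   downsampling layer. A block averages feature signals that have
   passed through different numbers of 3×3×3 convolution units
   (convolution → batch norm → ReLU) and re-attaches the block input as
   a residual:

       F(x) = ½(conv²(x) + conv(x))
       y    = x + ½(F₂(F₁(x)) + conv(x))

   All seven convolution units have independent weights; input and
   output shape and channel count are identical. The prose description
   of the block admits more than one wiring; this composition — two
   successive fusion stages, averaged with a single convolution of the
   input, plus an identity residual — follows the order of operations
   as described, with "combined with the input" read as element-wise
   addition (a relocated residual connection). The block sits behind
   one class so alternative wirings can be swapped in.

2. **A parallel distance-transform decoder.** Both decoders are
   structurally identical (transposed-convolution upsampling, skip
   concatenation from the matching encoder level, one convolution unit
   per level); the mask head is a 1×1×1 convolution to 4 channels with
   a softmax, the distance head a 1×1×1 convolution to 3 channels with
   a sigmoid. The decoders share no weights; both receive the same skip
   features. The distance task regularizes the mask task through the
   shared encoder.

### Distance-map target

For each foreground class the regression target is the unsigned
interior Euclidean distance transform: 0 outside the class; inside, the
distance to the nearest non-class voxel, divided by the per-channel,
per-volume maximum. The normalization to [0, 1] matches the sigmoid
output range and makes the target invariant to tumor size. An absent
class (e.g. no enhancing tumor in a low-grade case) yields an all-zero
channel rather than an error. Distances are computed in voxel units by
default; a spacing-aware variant exists but the loss does not use
spacing. Targets are computed once per volume and cropped per patch, so
patch targets are globally consistent.

### Loss

    L_total = λ₁·L_mask + λ₂·L_dist,    defaults λ₁ = λ₂ = 1

L_mask is a weighted categorical focal loss: per voxel, on the true
class c, −W_c·log(p_c)·(1−p_c)^γ with γ = 2 and class weights
(0.1, 1, 1, 1) — background down-weighted ten-fold, all three tumor
classes at 1. The weight applies per one-hot channel inside the voxel
average. L_dist is the squared error between the sigmoid prediction and
the target. Two aggregation choices are deliberately "mean":

* the distance loss is printed in the source formulation as a sum over
  the voxel set but described as mean squared error; the default here
  is the mean (stable across patch sizes), with `distance_reduction="sum"`
  available;
* the focal loss voxel aggregation is likewise unstated; mean is used.

Probabilities are clipped to [1e-7, 1−1e-7] before the log. Both losses
return analytic gradients with respect to the activated outputs; the
gradient of the focal term on the true class is
−W_c·[(1−p)^γ/p − γ(1−p)^{γ−1}·log p]/N, verified against finite
differences in the tests.

The ablation variants mirror the original comparison structure:
`model_I` removes the fusion blocks (strictly fewer parameters),
`model_II` sets λ₁ = 1, λ₂ = 0.1.

## Numerical engine

No deep-learning framework is used: `mtseg.nn` is a compact numpy CNN
engine with explicit backpropagation — 3D convolution (im2col lowered
to BLAS matrix products; stride 1 with symmetric padding, or stride
equal to kernel for non-overlapping 2×2×2 down/upsampling, where the
backward pass is an exact inverse reshape), transposed convolution,
batch normalization (momentum 0.1, eps 1e-5), instance normalization,
ReLU, and Adam (β₁ = 0.9, β₂ = 0.999, eps 1e-8). Weights use He
initialization from a seeded generator; arrays are float32 in
training, and every layer's gradient is validated against float64
central differences at 1e-5 relative tolerance. Softmax subtracts the
per-voxel maximum; sigmoid uses the numerically stable two-branch form.

### Normalization choice

The architecture default is batch normalization. At batch size 1,
batch normalization in training mode is mathematically identical to
instance normalization (per-channel statistics over one sample's
spatial axes); the two differ only at inference, where batch norm
switches to running averages. With heavily tumor-biased patch sampling
those running averages are not representative of background-only
inference patches, and we observed erratic full-volume predictions
(over-segmentation with near-perfect sensitivity) that vary strongly
with the seed. The desk profile therefore uses instance normalization:
training is unchanged, and inference uses exactly the statistics
training used. Full-scale configurations with larger batches can keep
batch norm.

## Preprocessing

Each modality is Z-scored independently: (X − mean)/sd with statistics
over the whole volume (the literal reading of the standardization
formula); a brain-only option (`nonzero_only`) restricts the statistics
to non-zero voxels, since the region the statistics cover is not
specified in the source. A constant channel returns zeros with a
warning. Standardization happens on the full volume before patching.
Labels are one-hot encoded with label 4 on channel 3. Training patches
are drawn randomly with 50% forced to intersect tumor (class imbalance
makes unbiased sampling wasteful); inference uses a deterministic
overlapping grid (default 50% overlap), averages softmax probabilities
over overlapping patches, and takes the per-voxel argmax (ties resolve
to the lower channel index). Full-scale patches are 128×128×64; the
desk profile uses 32³.

## Evaluation

Dice = 2TP/(FN+FP+2TP), sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP) on the binarized region masks. Empty-region conventions
follow the challenge: both masks empty → Dice 1; ground truth empty but
prediction not → Dice 0. HD95 is the 95th percentile (linear
interpolation) of voxel-to-nearest-voxel distances, symmetrized by the
maximum of the two directions — the challenge-standard robust reading
of the classical max–min Hausdorff distance. Sensitivity/specificity
with undefined denominators and HD95 with an empty mask are reported as
NaN and excluded from summary means rather than coerced to 0.
Post-processing applies only to ET: a prediction with fewer than 500
enhancing voxels (strict inequality) has them all relabeled to necrosis
— the one TC label that is not ET — so the WT and TC binary masks are
provably unchanged.

## Synthetic phantoms

The generator emulates the BraTS data contract, not MRI physics: a
brain ellipsoid (zero background, matching the skull-stripped
convention) containing nested axis-aligned ellipsoids — edema enclosing
a tumor core whose outer shell is enhancing tumor and whose interior is
necrosis, reproducing the ring-enhancement pattern the labels encode.
Per-axis radius jitter (±20%) and a random center stand in for shape
and position variability. Intensities come from a per-tissue,
per-modality contrast table plus Gaussian noise (sd 10 against tissue
contrasts of 30–85): edema bright on FLAIR/T2, the enhancing rim bright
on T1-CE, necrosis dark on T1/T1-CE. The table values are conventions
chosen to give a contrast-to-noise ratio a segmentation network can
exploit without being trivial. Defaults: 64³ volumes, radii (13, 8, 5)
voxels; the full 240×240×155 geometry is supported but not default.
Everything is a pure function of (spec, seed); per-case seeds are
spawned from the master seed.

What the phantoms do **not** model: anatomical tissue structure, bias
fields, partial-volume effects, multi-focal or irregular tumors,
inter-scanner intensity variation, registration artifacts. Passing the
end-to-end phantom check therefore demonstrates that the pipeline —
preprocessing, architecture, joint loss, inference, evaluation — is
wired correctly and can learn modality-dependent contrast, not that it
reaches any particular accuracy on clinical data.

## Training procedure

Adam with initial learning rate 1e-4 halved every two traversals of the
training set; per-traversal reshuffling; loss and mean foreground Dice
logged every 10 steps; checkpoints and a sample prediction/ground-truth
slice exported every 1000 steps; training aborts on a non-finite loss.
The full-scale schedule (500k steps) is configuration, not the tested
path.

The desk-scale profile (`desk_train_config` / `run_desk_experiment`)
is the package's own scaled-down study: 20 training and 5 held-out 64³
phantoms, 3 encoder levels, 8 base filters, instance normalization (see
above), 32³ patches, batch 1, 5 patches per case, 6 traversals (600
steps), initial learning rate 1e-3 (raised from 1e-4 because the run is
three orders of magnitude shorter; the halving schedule is unchanged).
On one CPU core this trains in roughly 9 minutes and reaches held-out
whole-tumor Dice ≥ 0.70, the regression bar used by the end-to-end
test — a property check on the pipeline, not a reproduction of any
published benchmark figure.

## Known limitations

* The numpy engine is single-device and unoptimized beyond BLAS
  lowering; full-scale BraTS training is out of its practical range.
* Batch statistics with batch size 1 make batch norm act closer to
  instance norm during training; running statistics are still tracked
  for evaluation mode.
* The fusion-block wiring is one defensible reading of its prose
  description; the class isolates it so alternates can be compared.
* Phantom realism is deliberately minimal (see above).
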