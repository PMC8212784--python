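# mtseg — multi-task volumetric brain-tumor segmentation

`mtseg` segments gliomas in multimodal 3D MRI (BraTS-style cases: four
co-registered contrasts FLAIR / T1 / T1-CE / T2 plus labels
{0 background, 1 necrosis, 2 edema, 4 enhancing tumor}). It is aimed at
medical-image-analysis researchers who want a transparent, fully
testable implementation of a dual-decoder segmentation framework —
including preprocessing, training, inference and challenge-convention
evaluation — that runs end to end on a laptop CPU via a built-in
synthetic phantom generator, with no dataset download and no GPU
framework dependency.

## The model

A V-Net-style fully convolutional network with a shared encoder and two
parallel decoders:

* the **mask decoder** classifies every voxel (softmax over 4
  channels);
* the **distance decoder** regresses, per foreground class, the
  normalized interior Euclidean distance transform D(x) ∈ [0, 1]
  (sigmoid over 3 channels), regularizing the mask boundaries through
  the shared encoder.

The encoder places a **multi-depth fusion block** before each
downsampling layer. With conv a (3×3×3 convolution, batch-norm, ReLU)
unit, the block computes

    F(x) = ½(conv(conv(x)) + conv(x))
    y    = x + ½(F₂(F₁(x)) + conv(x))

mixing feature signals of different depths and keeping a residual path;
input and output shapes are identical.

Training minimizes

    L_total = λ₁·L_mask + λ₂·L_dist

where L_mask is a class-weighted categorical focal loss
−W_c·log(p_c)·(1−p_c)^γ (γ = 2, background weight 0.1, tumor classes 1)
and L_dist is the mean squared error of the distance prediction.
Defaults λ₁ = λ₂ = 1; ablation variants remove the fusion blocks
(`model_I`) or set λ₂ = 0.1 (`model_II`).

Evaluation follows the BraTS conventions over the nested regions
ET = {4}, TC = {1, 4}, WT = {1, 2, 4}: Dice, sensitivity, specificity,
95th-percentile Hausdorff distance, the empty-ET Dice conventions, and
the post-processing rule that relabels fewer than 500 predicted
enhancing voxels to tumor core.

The network runs on a small numpy CNN engine with explicit
backpropagation (`mtseg.nn`); gradients are verified against finite
differences in the test suite.

## Worked example

```python
from mtseg.train import run_desk_experiment

result = run_desk_experiment(seed=1, n_train=20, n_test=5, epochs=6)
log, table = result["log"], result["metrics"]
print("loss:", round(log.head(5)["loss_total"].mean(), 3),
      "->", round(log.tail(5)["loss_total"].mean(), 3))
mean = table[(table.case_id == "__mean__") & table.postprocessed].set_index("region")
print("held-out WT Dice:", round(mean.loc["WT", "dice"], 3),
      "HD95:", round(mean.loc["WT", "hausdorff95"], 2))
```

This generates 25 synthetic 64³ phantom cases (nested
edema/core/enhancing-rim ellipsoids with modality-dependent contrast),
trains the full model for 600 steps on 32³ patches (about 9 minutes on
one CPU core), and evaluates the 5 held-out cases. Output:

```
loss: 0.467 -> 0.042
held-out WT Dice: 0.809 HD95: 29.49
```

i.e. the joint loss drops by an order of magnitude and the whole-tumor
region is recovered with Dice 0.81 on unseen phantoms (enhancing tumor
0.84, tumor core 0.74 in the same table; the HD95 tail reflects a few
scattered false-positive voxels far from the tumor).

The same pipeline is scriptable from the shell:

```bash
mtseg simulate --n 25 --shape 64 --seed 1 --out phantoms/
mtseg train --data phantoms/ --out run/ --variant full --seed 1
mtseg predict --checkpoint run/model_final.npz --in phantoms/ --out preds/
mtseg evaluate --checkpoint run/model_final.npz --data phantoms/ --out metrics.csv
```

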