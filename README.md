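# ssdr — self-supervised sparse-view 3D DSA reconstruction

Rotational 3D digital subtraction angiography (3D-DSA) normally
reconstructs a cerebrovascular volume from ~133 projection images by
filtered back-projection, exposing the patient to the full rotational
radiation dose. `ssdr` implements a self-supervised deep-learning
alternative that reconstructs the volume from **ultra-sparse view sets
(4–12 projections)** — roughly 1/16.7 of the dose at 8 views — without
ever seeing a 3D label. It is aimed at researchers in tomographic
image reconstruction who want a fully tested, desk-scale (CPU-sized)
implementation of the method, exercised end to end on synthetic
vascular phantoms.

## The method

Given projections X₁…X_N at view angles θ₁…θ_N, a cascaded volumetric
network F predicts the volume

    F(X₁,…,X_N, θ₁,…,θ_N) = Y_pred,

and is trained purely by **projection consistency**: the prediction is
re-projected with a differentiable parallel-beam maximum-intensity
projector P and compared with the inputs,

    Loss = Σᵢ ‖P(Y_pred; θᵢ) − Xᵢ‖²₂ .

No 3D supervision is needed. The pipeline is:

1. **Multi-view preprocessing** — each view is normalised to [0, 1],
   resized per stage, smeared back along its ray direction into a 3D
   channel ("dimensional ascending"), and cropped to the common
   cylindrical support of the 180° sweep.
2. **Two-stage cascade** — a low-resolution 3D U-Net reconstructs a
   coarse volume; a full-resolution 3D U-Net refines it, taking the
   upsampled coarse prediction as an extra input channel. A
   view-shared convolution lifts each channel to feature maps fused by
   an element-wise minimum (the intersection prior of smear
   back-projection), so the parameter count is independent of the
   number of views.
3. **Post-processing** — Z-slabs whose mean predicted intensity exceeds
   a background-plausibility threshold (default 0.01) are zeroed.
4. **Evaluation** — MSE, MAE, PSNR = 20·log₁₀(max(ref)/√MSE), and a
   global luminance·contrast·structure SSIM.

Because clinical angiograms are protected, the package ships a seeded
synthetic phantom generator (sparse bright tubular trees with optional
aneurysm bulges and background noise, ≤10 % foreground voxels) that
stands in for the training and test data. Everything — including the
3D convolutions and their gradients — runs on plain numpy; no GPU or
deep-learning framework is required.

## Worked example

```python
from ssdr import (PhantomSpec, make_dataset, make_scheme, project_set,
                  crop_common_support, evaluate,
                  SelfSupervisedReconstruction, TrainConfig,
                  CascadeConfig, UNetConfig)

# ten 64^3 vascular phantoms: eight for training, two held out
vols = make_dataset(10, PhantomSpec(), base_seed=10_000)
scheme = make_scheme(8, coverage_span=180.0)   # 8 views over 180 deg

# desk-scale cascade (the library defaults are the clinical-scale
# depth-4 / 16-feature recipe, far heavier than a CPU demo needs)
desk_net = UNetConfig(depth=2, base_features=4)
model = SelfSupervisedReconstruction.from_volumes(
    vols[:8], scheme, low_shape=(32, 32, 32), high_shape=(64, 64, 64),
    cascade_config=CascadeConfig(stage1=desk_net, stage2=desk_net),
    train_config=TrainConfig(lr_stage1=2e-3, lr_stage2=2e-3, lr_decay=0.98,
                             epochs_stage1=60, epochs_stage2=12))
fit = model.fit(seed=0)
print(fit.summary())

for gt in vols[8:]:
    rec = fit.reconstruct(project_set(gt, scheme))
    r = evaluate(crop_common_support(gt), rec)
    print(f"held-out SSIM {r.ssim:.3f}  PSNR {r.psnr:.2f} dB")
```

Output from this exact script (about six minutes on one CPU core):

```
Self-supervised sparse-view reconstruction
============================================
views:            8 (coverage 180 deg)
training cases:   8
grids:            low (32, 32, 32), high (64, 64, 64)
mode:             cascade
parameters:       45434
stage1: epochs 60, final train loss 3.934e-03, best val loss 7.152e-03 @ epoch 33
stage2: epochs 12, final train loss 7.091e-03, best val loss 5.777e-03 @ epoch 11

held-out SSIM 0.910  PSNR 28.96 dB
held-out SSIM 0.879  PSNR 33.06 dB
```

The training loss is the mean squared mismatch between the
reconstruction's projections and the input views; the held-out SSIM ≈
0.9 says the model generalises to unseen phantoms from the projection
consistency signal alone.

A command-line interface mirrors the library
(`ssdr phantom | project | train | reconstruct | postprocess |
evaluate | experiment`); see `ssdr --help`.

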