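# mfnet

Segmentation of **choroidal neovascularization (CNV)** in retinal optical
coherence tomography (OCT) B-scans. CNV — new choroidal vessels breaking
through Bruch's membrane — appears in OCT as an irregular hyperreflective
region with a blurred boundary, large shape variability, and heavy
multiplicative speckle noise. Accurate pixel-level delineation supports
diagnosis and treatment monitoring, but those image properties defeat
generic encoder–decoder segmenters, and pixel-level annotations are scarce.

This package implements **MF-Net**, a multi-scale information-fusion
encoder–decoder network for this task, together with its pseudo-label
semi-supervised variant **SemiMF-Net**, as a tested NumPy library with a
CLI. A seeded synthetic B-scan generator emulates the layered, speckled
appearance of real scans with ground-truth lesion masks, so the full
pipeline — training, cross-validation, pseudo-labelling, evaluation — runs
end to end with no external dataset or GPU.

## The model

The backbone is a U-shaped encoder–decoder **without** same-level skip
connections: four encoder stages (two 3×3 conv + BN + ReLU, then 2×2 max
pooling; channels double each stage), three decoder stages (bilinear ×2
upsampling + 3×3 conv + BN + ReLU), and a sigmoid head. Two modules are
added:

* **MAD** (multi-scale adaptive-aware deformation), at the top of the
  encoder. Four parallel branches (1×1 squeeze to c/4, then 3×3 convolution
  with dilation rate 2k−1 ∈ {1, 3, 5, 7}) are concatenated and fused by a
  3×3 **deformable convolution** whose sampling offsets are predicted from
  the features, giving

  B = Conv_deform( concat_k( conv_dil@2k−1( A^k ) ) ).

  B is re-weighted by a spatial gate S = σ(conv7×7([max_c B; mean_c B])) ∈
  R^{1×h×w} and a channel gate C = σ(FC(conv1×1([gmax B; gmean B]))) ∈
  R^{c×1×1}, combined through an adaptive residual

  O = B ⊕ conv( λ·B ⊗_spatial S ⊕ γ·B ⊗_channel C ),

  with learnable scalars λ, γ initialised to 1.0.

* **SDA** (semantics–details aggregation) replaces the two shallow skip
  connections. Upsampled deeper semantics F gate the encoder detail E
  multiplicatively before adding the decoder stream D:

  S^k = Conv( F^k @2 ) ⊗ E^{3−k} ⊕ D^{3−k},   k = 1, 2.

  No skip paths exist from the two deepest encoder stages.

Training minimises the joint objective **L = L_Dice + L_BCE**; evaluation
reports **DSC = 2TP/(FP+2TP+FN)**, **SEN = TP/(TP+FN)** and
**JSC = TP/(FP+TP+FN)** in percent (mean ± SD across images or folds), with
paired t-tests for fold-level comparisons. SemiMF-Net pretrains on labelled
scans, binarises its predictions on unlabelled scans into pseudo-labels, and
retrains on the pooled set under **L_Pseudo + β·L_Real** (β = 1).

The network, including the deformable convolution and full backpropagation,
is implemented on a small NumPy reverse-mode autodiff core
(`mfnet.autodiff` / `mfnet.nn`), so the package has no deep-learning
framework dependency and runs reproducibly on one CPU.

## Worked example

Train a reduced network on synthetic scans and compare with an Otsu
thresholding baseline:

```python
from dataclasses import replace
import numpy as np

from mfnet import (NetworkConfig, SynthParams, TrainConfig, evaluate_model,
                   otsu_baseline, segmentation_metrics, synth_samples,
                   train_supervised)

# 60 synthetic speckle-noisy B-scans with one CNV-like lesion each
params = SynthParams(image_size=(64, 64), seed=0)
train = synth_samples(48, params)
test = synth_samples(12, replace(params, seed=10_000))

config = TrainConfig(epochs=8, seed=0,
                     network=NetworkConfig(base_channels=16, input_size=(64, 64)))
checkpoint, history = train_supervised(config, train, test)

report = evaluate_model(checkpoint, test)
otsu = np.mean([segmentation_metrics(otsu_baseline(s), s.mask)[0] for s in test])
for name, mean, sd in zip(("DSC", "SEN", "JSC"), report.mean, report.sd):
    print(f"{name}: {mean:.2f} +/- {sd:.2f}")
print(f"Otsu baseline DSC: {otsu:.2f}")
```

Output (about a minute on one CPU):

```
DSC: 87.88 +/- 5.26
SEN: 87.07 +/- 6.27
JSC: 78.71 +/- 7.94
Otsu baseline DSC: 34.49
```

The network reaches a held-out Dice of ~88% on this small task while plain
intensity thresholding — which cannot separate the bright lesion from the
bright retinal bands — stays near 34%. Larger runs (200 training scans at
128×128, 15 epochs) reach held-out Dice above 95%.

The same workflow is available from the shell:

```bash
mfnet synth --out data/train --n 100 --size 128 --seed 0
mfnet synth --out data/test  --n 30  --size 128 --seed 90000
mfnet train --data data/train --out ckpt.npz          # YAML config optional
mfnet evaluate --checkpoint ckpt.npz --data data/test --out per_image.csv \
      --overlays overlays/    # TP yellow, FP red, FN blue
```

Other subcommands: `cross-validate` (k-fold harness with per-fold CSVs),
`predict` (float32 probability TIFFs + binarised PNGs), `pseudo-label`, and
`train-semi` (the full three-step semi-supervised pipeline).

## Scope

The UCSD OCT dataset used in the original study (1,522 annotated CNV
B-scans, 2,560 unlabelled) is not bundled; applying the package to it only
requires pointing the CLI at directories of PNG images and masks.
Comparison networks (UNet, CE-Net, CPFNet, …) and inference-time
benchmarking are out of scope.
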