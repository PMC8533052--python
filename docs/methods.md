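# Methods

## Task and model

The package segments choroidal neovascularization (CNV) lesions in
grayscale retinal OCT B-scans: input an image in [0, 1], output a per-pixel
lesion probability map of the same size, binarised at 0.5 for evaluation.

MF-Net is a U-shaped encoder–decoder with four encoder stages and three
decoder stages plus a head. Stage k of the encoder produces
`base_channels · 2^(k−1)` channels at 1/2^k of the input resolution
(defaults: 64/128/256/512 at 1/2 … 1/16). Same-level skip connections are
deliberately absent from the backbone; the two shallow skips are
reconstructed by SDA modules and the deepest features pass through the MAD
module. The design decisions that the architecture description leaves open
were resolved as follows:

* **Encoder blocks** are (3×3 conv → batch-norm → ReLU) ×2 followed by 2×2
  max pooling, trained from scratch (no pretrained weights, for exact
  reproducibility). A `pretrained_encoder` config hook can warm-start the
  encoder from a `.npz` of matching arrays.
* **Decoder blocks** use bilinear ×2 upsampling followed by 3×3 conv +
  batch-norm + ReLU; transposed convolutions were avoided because of
  checkerboard artifacts. Channel counts mirror the encoder.
* **Upsampling** everywhere (decoders, SDA, head) is exact ×2 bilinear with
  the half-pixel-centre convention, implemented as a separable two-tap
  stencil (weights 0.75/0.25, edge-clamped) with an exact adjoint for the
  backward pass.
* **MAD** branch squeeze width is c/4 per branch so concatenation restores
  c channels. The spatial-attention convolution is 7×7 (the customary large
  kernel for spatial gating); the channel attention uses a 1×1 squeeze
  (2c→c) and a c→c fully connected layer. The deformable convolution's
  offset predictor (a 3×3 conv producing 18 offset channels) is
  zero-initialised, so at construction the layer equals a standard 3×3
  convolution — an identity the tests assert — and offsets are learned
  jointly. λ and γ in the adaptive residual start at 1.0.
* **SDA** contains a single bare 3×3 convolution (F's channels → E's
  channels) and no normalisation or activation, keeping the zero-gate
  (E = 0 ⇒ S = D) and unit-gate (conv ≡ 1 ⇒ S = E + D) identities exact.
* **Input size** defaults to 256×256 (configurable, both dims divisible by
  16); real scans of other sizes are resized bilinearly (images) /
  nearest-neighbour (masks).

## Objective and metrics

The training loss is `L = L_Dice + L_BCE`, unweighted. Dice is smoothed
with ε = 1e-6 to define the empty-mask case:
`L_Dice = 1 − (2Σ XY + ε)/(ΣX + ΣY + ε)`. BCE uses **mean** reduction over
pixels (a sum would make the BCE term scale with image area while Dice
stays in [0, 1]; the mean keeps the two components comparable across input
sizes — a deliberate, documented choice). Predictions are clamped to
[1e-7, 1−1e-7] inside BCE.

Evaluation metrics are computed from exact pixel confusion counts: DSC,
SEN and JSC in percent. When a metric's denominator is zero the value is
100 if both masks are empty and 0 otherwise. Summaries report mean ±
sample SD (ddof = 1). Fold-level comparisons use a two-sided paired t-test
(SciPy), with conventions for degenerate inputs: identical vectors → p = 1;
constant nonzero difference (infinite t) → smallest positive float.

Cross-validation deals samples to folds by shuffling with a seed and
assigning floor(N/k) ids to each of the first k−1 folds and the remainder
to fold k — the unique scheme that splits 1,522 scans 4 ways as
(380, 380, 380, 382).

## Semi-supervised variant

SemiMF-Net: (1) pretrain on the labelled set; (2) predict on unlabelled
scans and binarise at 0.5 (no confidence filtering) to obtain pseudo-masks;
(3) retrain on the pooled set under `L_Pseudo + β·L_Real`, β = 1 by
default. Loss accounting is per sample over the whole batch: each
provenance component is the sum of its samples' joint losses divided by the
**total** batch size, so at β = 1 the objective equals the uniform mean
joint loss over the pooled batch (asserted to 1e-6 in the tests). With the
per-provenance-mean alternative that identity cannot hold; the per-batch
accounting was chosen for exactly that reason. Retraining warm-starts from
the pretrained weights (`warm_start=False` restarts from scratch); one
pseudo-labelling round is performed; mixed batches are drawn from the
pooled set without provenance balancing.

## Optimisation

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with learning rate 5e-4 and L2
weight decay 1e-4 added to the gradient; batch size 4; 50 epochs by
default. No learning-rate schedule and no data augmentation by default;
an `epoch_hook` and the config dataclasses expose both. Model selection
keeps the epoch with the best validation Dice (final-epoch weights when no
validation set is given). Weight initialisation is He-normal from a
generator seeded by `config.seed`; shuffling uses a derived generator, so
runs are bit-reproducible.

## Computational core

No deep-learning framework is used: `mfnet.autodiff` is a tape-based
reverse-mode autodiff engine over NumPy arrays (float32), with stride-1
convolutions evaluated as per-tap channel GEMMs (an im2col path for very
thin inputs), batch normalisation, 2×2 max pooling, the bilinear ×2
resampler, channel/spatial reductions, and a 3×3 deformable convolution
with exact gradients for inputs, kernels **and** sampling offsets (the
input-gradient bilinear scatter uses a small numba kernel). Every operation
is verified against central-difference numerical gradients at 1e-6 relative
tolerance. Single-threaded NumPy makes all results deterministic for a
fixed seed and platform.

## Synthetic data

`synthetic_data` generates B-scans that reproduce the properties that make
CNV segmentation hard:

* a curved, layered band structure (default 6 bands, intensities 0.15–0.65
  with brighter top/bottom bands) over a dark vitreous and a dim choroid;
* one simply-connected hyperreflective lesion (intensity 0.8–0.95) per
  image: a radial polygon with low-order Fourier boundary perturbations and
  lateral elongation (aspect 1.2–2.2), rejection-sampled until its area
  fraction lies in `lesion_area_frac` (default 3–12% of the image) and it
  is a single 8-connected component; the stored mask is the exact pre-blur
  polygon raster;
* a soft lesion boundary from Gaussian-blurred compositing (σ = 1.5 px);
* multiplicative gamma speckle with mean 1 and variance
  `speckle_strength` (default 0.15), the standard model for coherent
  imaging noise.

What the generator does **not** emulate: real retinal anatomy (vessel
shadows, foveal pit, pathology other than one lesion), scanner-specific
intensity statistics, multiple or non-lesion hyperreflective structures,
and annotation noise. Passing the synthetic benchmarks therefore shows the
architecture, losses and training loop are implemented correctly and can
learn a non-trivial lesion-vs-bright-bands discrimination (Otsu
thresholding scores ~30–40 DSC, the trained network >90); it does not
certify clinical-grade accuracy on real OCT data.

## Problem sizes in tests and the acceptance script

Desk-scale runs use reduced settings chosen to exercise every code path
with meaningful learning: the supervised benchmark trains base-16 networks
on 200 synthetic 128×128 scans for 15 epochs (tests) or 120 scans for 10
epochs (acceptance script); the semi-supervised benchmark uses 50 labelled
+ 100 unlabelled 64×64 scans for 8 epochs (tests) or 40 + 80 for 6 epochs
(script). Full-scale defaults (base 64, 256×256, 50 epochs) remain the
package defaults.

## Known limitations

* CPU-only; a 256×256 base-64 network trains orders of magnitude slower
  than a GPU implementation, so full-scale experiments on the 1,522-scan
  dataset are impractical here.
* Stride-1, odd-kernel, "same"-padding convolutions only (all the
  architecture needs); no groups or transposed convolutions.
* The deformable convolution follows the single-group formulation (offsets
  shared across input channels), without the modulation term.
* Batch-norm statistics are per-process; checkpoints store running
  statistics, so eval-mode inference is deterministic, but resuming
  training mid-epoch is not supported.
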