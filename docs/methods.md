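# Methods

## Model

The translator is a bidirectional cycle-consistent adversarial network for
unpaired 2D MR ↔ CT slices. Two generators (MR→CT and CT→MR) and two patch
discriminators are trained jointly. Per direction the generator objective is

```
L_sCT = λ_G · mean[(D_CT(G(MR)) − 1)²]          least-squares adversarial
      + λ_cycle · mean|MR − G_B(G(MR))|          cycle consistency
      + λ_idt · mean|CT − G(CT)|                 identity
      + λ_mind · mean|MIND(MR) − MIND(G(MR))|    structural conservation
```

and each discriminator minimises
`λ_D · (mean[D(fake)²] + mean[(D(real) − 1)²])`. Weights are
λ_G = 1, λ_D = 0.5, λ_cycle = 10, λ_idt = 5, λ_mind = 1; every reduction is a
mean over pixels and batch so the weights are scale-free across image sizes.
Adversarial targets are exactly 1 (real) and 0 (fake).

### MIND

The modality-independent neighbourhood descriptor at pixel *x* for offset
*r* in the 8-neighbourhood is `exp(−Dp(x, x+r)/V(x))`, with `Dp` the sum of
squared differences between the 3×3 patches at *x* and *x + r* and `V` the
mean of `Dp` over the 8 offsets. `Dp` is computed for all pixels at once as
an all-ones box filter over the squared difference between the image and its
translated copy; a literal double-loop oracle in the test suite pins the two
forms together to 1e-6. Note the box filter must act on the *squared*
difference — filtering the raw difference would not reproduce the patch
distance.

Numerical choices: translations and the box filter use replicate (edge)
padding; `V` is clamped below at 1e-3 of its spatial mean (absolute floor
1e-12) so constant regions are well defined; channels are normalised so the
per-pixel maximum channel is 1 (the original descriptor's convention), with
a plain 1/8 prefactor selectable. The per-pixel prefactor *n* and any hidden
weight on the MIND term are exposed (`MINDConfig.normalization`,
`LossWeights.lambda_mind`) and default to max-one and 1. The descriptor is
exactly invariant to positive affine intensity maps (both `Dp` and `V` scale
by a², cancelling), which is what lets it compare images across modalities.

The same computation exists twice: a numpy implementation for evaluation and
a differentiable mirror inside the autodiff engine for training; a test pins
them to each other at 1e-6.

### Generators and discriminators

`swin_unetr_2d`: a 7×7 convolutional stem, a stride-2 patch embedding, then
a U-shaped encoder–decoder of shifted-window attention stages (window 4,
alternating unshifted/half-shifted partitions with the standard cyclic-shift
attention mask; layer normalisation; 4× MLP with GELU). Decoding uses
nearest upsampling, skip concatenation and one attention block per stage; a
final 7×7 convolutional head maps back to one channel with tanh. Relative
position bias is omitted (small windows, desk scale). `resnet_baseline`: the
classic residual translation generator — 7×7 stem, two stride-2
downsamplings, residual blocks with instance normalisation, nearest-upsample
decoding, 7×7 head, tanh. Both variants satisfy one contract (1-channel
[−1, 1] grid in and out, same shape) and are interchangeable behind the
ablation switch. The discriminator is a strided patch discriminator (odd
5-pixel kernels, instance norm, leaky ReLU) emitting a spatial score map
with no output nonlinearity.

Networks run on `sctkit.nn`, a compact reverse-mode automatic
differentiation engine over numpy arrays (conv via sliding windows + einsum,
attention via batched matmul, Adam with β₁ = 0.5). Gradients are verified
against central finite differences in the test suite. Desk-scale capacity
(embed dim 12, two stages, width-8 baseline) trains in minutes on one CPU;
paper-scale capacity is a configuration, not a different code path.

### Optimisation

Adam, learning rate 1e-4, β = (0.5, 0.999), batch size 1. The rate is
constant through epoch 30 and then decays linearly to exactly zero at epoch
100 (1-based epochs; the first decayed epoch is 31, so lr(65) = 5e-5).
Generators update first on the combined bidirectional objective, then each
discriminator on its own loss against a 50-image replay pool of past fakes.
Update order, pool, β₁ and batch size follow the conventions of unpaired
adversarial translation; the optimisation schedule (rate, decay window,
epoch count) is as published. Training aborts with a diagnostic on any
non-finite loss. Fixed seeds reproduce loss trajectories bit-for-bit on a
fixed machine.

## Preprocessing

CT: clip to [−1024, 3071] HU; body mask = largest connected component above
−300 HU (a mid fat/air threshold, standard for body contouring) with
interior holes filled so bowel gas stays inside the mask; everything outside
set to −1024. MR: quantile-mapping histogram matching against a caller-
chosen reference (the matching reference is deliberately a parameter).
Network scaling: CT uses the fixed affine [−1024, 3071] → [−1, 1], so HU are
recovered from generator output exactly by the inverse map; MR uses a
per-image robust (0.5th/99.5th percentile) rescale. Resampling uses
pixel-center coordinates with the physical field-of-view centre preserved,
linear for intensities and nearest for masks.

## Phantom

The synthetic cohort emulates the data regime of an unpaired abdominal
study: 2D slices, default 256×256 at 0.83 mm (tests use 64×64), ellipse
anatomy (body with a fat rim, liver, stomach, two kidneys, one spine), and
per-slice jittered geometry. CT intensities are class-wise HU means
(gas −800, fat −100, soft 40, liver 60, kidney 30, bone 700) plus N(0, 20)
noise, clipped to the scanner range; MR intensities use a *reversed*
ordering (bone dark, fat bright) — so no affine map connects the modalities —
times a smooth multiplicative bias field `exp(0.2 · low-order polynomial)`
(emulating B0 inhomogeneity) plus N(0, 15) noise. Intensity means and noise
levels are configurable constants chosen once as plausible for the tissue
classes; nothing downstream depends on their exact values.

Anatomical discrepancy, the dominant real-world confound in abdominal MR/CT
pairs, is modelled on gas only: `discrepancy_level` is the fraction of gas
pockets painted into exactly one modality's label map (rounded count, so
level 0.5 with 8 pockets flags exactly 4). Test cohorts split half/half into
Group 1 (level 0, aligned anatomy) and Group 2 (the configured level).

Dose fields are sums of three anisotropic Gaussian blobs centred in the
target structure (default liver), scaled so the maximum equals the
prescription (25 Gy default), optionally attenuated by 25% around smoothed
gas — the mechanism by which modality-unique gas perturbs dose and separates
the groups dosimetrically, standing in for density effects a treatment
planning system would compute. With attenuation off the grid integral
matches the closed-form truncated-Gaussian integral to 1%. GTV = target
organ, PTV = GTV dilated 5 mm, OARs = kidneys and spine.

What the phantom does *not* model: realistic organ shapes, respiration or
peristalsis, 3D anatomy, MR artifacts beyond the bias field, and any actual
dose *calculation* from HU. Passing tests therefore demonstrate the
correctness of the algorithms and the qualitative behaviour of the pipeline
— not clinical-grade synthesis quality, which requires real cohorts at full
scale.

## Evaluation

Image metrics are computed strictly within the body mask: MAE (HU); PSNR
over the fixed 4095 HU clip width (per-image ranges would break
cross-case comparability), capped at 100 dB for identical inputs; SSIM with
an 11×11 Gaussian window (σ 1.5, K1 = 0.01, K2 = 0.03), windows drawn from
the full arrays but averaged only over in-mask centres whose window fits the
image; KL divergence KL(planning-CT ‖ sCT) over 100-bin histograms on
[−1024, 3071] with 1e-10 additive smoothing and natural logs (direction,
binning and base are conventions, flagged in report headers). Method
comparison uses the two-sided Wilcoxon rank-sum test (exact distribution for
small tie-free samples, midrank normal approximation otherwise).

Gamma analysis: for every reference voxel at or above 10% of the
normalisation dose (maximum of the reference — the common delivery-QA
convention), γ² is minimised over candidate shifts within 2× the DTA on a
lattice of spacing/3 per axis, with linear interpolation of the evaluated
dose; a voxel passes iff γ ≤ 1. Local mode normalises the dose difference by
the voxel's reference dose, global mode by the normalisation dose. The
evaluated voxel set is identical across criteria, so rates are comparable;
an exhaustive brute-force oracle in the tests reproduces the pass rates
exactly at the same settings. Both 2D and 3D grids are supported.

DVH curves use direct counting (`V(d)` = percent of structure voxels with
dose ≥ d; no interpolation), as do V_x, D_mean and D_max. Relative DVH
differences are percent-of-reference, `100·(sCT − CT)/CT` (positive when the
sCT-based metric is larger); a percentage-point mode is provided because the
convention is ambiguous in practice; a zero reference reports NaN, not
infinity.

## Ablation harness

Four arms on one cohort and seed: `baseline` (residual generator),
`swin_only` (attention generator), `mind_only` (residual + MIND),
`proposed` (attention + MIND); arms differ in exactly those two switches.
The harness emits one table (rows = arms; columns = MAE/PSNR/SSIM/KL, the
test-set MIND distance between MR and sCT, and local/global gamma pass rates
at 1–3%/1–3 mm). Because phantom dose pairs are derived from CT-view vs
MR-view anatomy rather than from the generated images, the gamma columns
probe the anatomical-discrepancy effect and are shared across arms; the
image metrics and MIND distance are what separate the arms at desk scale.

## Problem sizes

The default test-suite runs use: training smoke at 20 pairs, 64×64, tiny
capacity, 10 epochs; the ablation at 8 pairs, 64×64, 10 epochs per arm;
gamma oracle checks on 16×16 grids; descriptor oracles on 12×12 images.
These sizes are the package's desk-scale working points — large enough for
the directional claims (loss descent, better-than-naive synthesis, group
ordering) to be visible, small enough to run on one CPU in minutes.

## Known limitations

* Desk-scale adversarial training is short; synthesized image quality is far
  from converged, and inter-arm differences in the structural (MIND)
  distance are small compared to its noise-driven floor — the phantom's
  sensor noise dominates the descriptor distance between a noisy MR and a
  smooth generated image, a real property of the descriptor at small patch
  size.
* At desk scale the MIND term lowers the structural drift of its own
  generator variant consistently (MIND-on beats MIND-off within each
  variant), but the *choice of generator* moves the MR-to-sCT structural
  distance by more than the loss term does, and the sign of that variant
  effect depends on the training conditions. Cross-variant orderings of the
  structural distance are therefore not reliable below full training scale.
* The phantom's dose model is a stand-in; no HU→dose calculation exists in
  the package, so dosimetric arm differences cannot emerge from image
  quality.
* 2D only; the clinical problem is volumetric.
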