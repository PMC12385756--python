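# Methods

This note documents the models and procedures implemented in `robustfood`,
the choices made where the design was genuinely open, and what the
desk-scale experiments do and do not show.

## Problem setting

Fine-grained food-image recognition suffers from two coupled difficulties:
classes look alike (inter-class similarity) while single classes vary
widely (intra-class variability), and real capture conditions add sensor
noise that erodes exactly the subtle texture cues that separate similar
dishes. The framework here attacks both at once: second-order (covariance)
feature statistics amplify subtle texture directions, an auxiliary
denoising task pushes the backbone toward noise-invariant features, and a
distillation stage transfers the resulting accuracy into a plain backbone
for cheap inference.

## Eigenvalue-enhanced global covariance pooling (EGCP)

Given a feature map `x ∈ R^{D×H×W}`, each channel is standardized over its
`N = H·W` spatial positions with guard `ε`, and per-channel precision
weights `w_d = 1/(σ_d² + ε)` are recorded — channels with large variance
(the ones noise inflates) are down-weighted. The weighted channel
covariance is

    P = (1/N) (W^{1/2} X̃)(W^{1/2} X̃)ᵀ,   W = diag(w_d),

with `X̃` the centered `D×N` normalized feature matrix. After
regularization `P_reg = P + εI`, eigendecomposition `P_reg = U Λ Uᵀ` and an
eigenvalue floor at `ε`, the spectrum is enhanced as `λᵉⁿ = log(1 + λ)`.
The map is concave with `log(1+λ)/λ` strictly decreasing, so small
eigenvalues — the directions carrying fine texture detail — gain relatively
more than dominant ones. A dynamic scaling factor

    S_F = ‖P_en^{1/2} exp(−P_en)‖_F = sqrt(Σ_i λᵢᵉⁿ e^{−2λᵢᵉⁿ})

modulates the output; the final descriptor is `A = (S_F + 1)·P_en^{1/2}`,
flattened row-major to length `D²`.

Numerical choices:

* all matrix functions are evaluated in the eigenbasis (`U f(Λ) Uᵀ`), valid
  because every spectrum involved is nonnegative; no iterative square-root
  scheme is used — at desk scale an exact symmetric eigendecomposition is
  cheaper and more accurate;
* every downstream quantity is a spectral function of `P_reg`, so the
  result is independent of the eigenbasis chosen for repeated eigenvalues
  (the tests assert basis-independence rather than pinning a basis);
* the implementation computes `S_F` from the assembled matrix and asserts
  the eigenvalue closed form to 1e−8 on every call — the identity doubles
  as an internal consistency check;
* `ε` defaults to 1e−5 and is exposed in `EGCPConfig`;
* the enhancement consumes the floored eigenvalues (the floor feeds the
  log), keeping the chain monotone and bounded away from `log(1+0) = 0`.

## Noise-adaptive recognition module (NARM)

One NARM attaches to one backbone stage and runs two branches on the same
tapped feature:

* **ARU** (classification): a feature-transformation bottleneck (1×1 conv →
  BatchNorm → ReLU → 3×3 conv, `C → D₂ → D`, with `D₂ = D/2` by default),
  EGCP pooling to a `D²` descriptor, then a classifier head
  `Linear(D² → D) → BatchNorm → ReLU → Linear(D → N)`, optionally with an
  extra hidden width `D′`. The descriptor has no spatial extent, so the
  head's "1×1 convolutions" are exactly linear layers.
* **RTU** (restoration): a progressive recovery chain of ×2 sub-pixel
  modules `ReLU(Conv3×3(PixelShuffle₂(x)))`, halving channels per module,
  closed by a linear 3×3 RGB projection; plus a low-level supplement of two
  3×3 convolutions applied to the noisy input (`3 → D″ → 3`, no
  intermediate activation). The restored image is the pixel-wise sum of the
  two outputs — an exact additive fusion the tests assert.

The per-stage upsampling count is `log2(image_size / stage_size)`, so every
NARM restores to full input resolution; at the full-scale 448-input /
28×28-stage geometry this recovers a four-module chain.

The joint loss is `L_NARM = α·L_rec + β·L_mse` with softmax cross-entropy
`L_rec` and pixel MSE `L_mse`; `(α, β) = (0.6, 0.4)` by default. The
restored image is not clamped inside the loss; evaluation clamps to [0, 1].

Restoration-specific initialization: the LFS convolutions start as
near-delta (pass-through) kernels and the PRM's RGB projection starts near
zero, so the restoration branch begins at the identity map and SGD only
has to learn the denoising correction. Identity-oriented initialization is
standard for restoration branches; without it the branch needs far more
steps than a desk-scale budget to reach even the noisy-input baseline.

## Weighted multi-granularity fusion (WMF) and staged training

The teacher taps the last stages of the backbone (three at full scale, two
in the tiny preset). Tapped features are 1×1-projected to a common width,
average-resampled to the deepest tap's grid, and fused as
`x* = Σ βᵢ xᵢ` with weights (0.2, 0.35, 0.45) emphasizing deeper stages; a
separate ARU classifies `x*`. When fewer taps exist than weights, the
deepest weights are kept and renormalized to sum to one.

Each batch performs S+1 backward passes in stage order — every NARM's
joint loss, then the fused classifier's cross-entropy — with gradients
accumulating into a single SGD update. Stepping once per batch keeps the
update independent of the within-batch loss order while preserving direct
supervision at every depth; NARM losses do propagate into the backbone
stages below them. The optimizer is SGD with momentum 0.9 and cosine
annealing `lr(t) = floor + ½(lr₀ − floor)(1 + cos(πt/horizon))`; global
gradient-norm clipping (default 5.0) stabilizes the deep restoration
chains, whose pixel-level losses otherwise produce occasional exploding
updates under momentum.

## Progressive temperature-aware feature distillation (PTAFD)

The trained teacher's fused head produces soft labels
`softmax(z_t / T)`; the student is trained with

    L = α·L_distillation + (1 − α)·L_student,   α = 0.5,

where `L_distillation = −Σ softmax(z_t/T) · log softmax(z_s/T)` (both sides
softened at the same temperature, the standard soft-label formulation) and
`L_student` is plain cross-entropy at `T = 1`. No `T²` gradient
compensation factor is applied — a deliberate deviation from common
distillation practice, matching the loss as specified. The temperature
follows a piecewise-linear schedule over the distillation phase, rising
from 0.5 to 2.0 by default (sharp first, smooth later); a falling schedule
is selectable because the two published descriptions of the schedule
disagree in direction. Phase 2 (default: the last 20 % of epochs) drops
the teacher and fine-tunes with cross-entropy only. An optional per-stage
feature-alignment term compares teacher and student stage features after
1×1 projection of the student to the teacher's width and global L2
normalization (scale-invariant MSE, mean over stages); it carries no
temperature — its "progressiveness" is the phase split itself.

## Metrics

Top-k accuracy uses descending-score rankings with ties broken toward the
lowest class index (stable sort), for cross-platform reproducibility.
Per-class precision/recall/F1 derive from the top-1 confusion counts;
macro-F1 is the unweighted class mean; zero-support classes get F1 = 0 and
a warning. Multi-seed results aggregate as mean ± sample (n−1) SD,
matching the usual five-seed reporting convention.

## Synthetic fixtures

The generator emulates the fine-grained regime procedurally: every class
is a texture recipe (smoothed-blob fields, oriented sinusoidal stripes, or
granular speckle) over an overlapping warm palette, with per-image jitter
of scale, orientation, brightness and palette. Classes therefore overlap
in mean color but differ in second-order texture statistics — learnable,
but not trivially by color pooling. Noise injection is zero-mean Gaussian,
independent per pixel and RGB channel, on the [0, 1] pixel scale (the only
scale on which σ = 0.10 is meaningful), applied to training inputs only,
clipped to [0, 1] by default (disabled inside moment tests), and
deterministic under (seed, image index). The preprocessing pipeline
(bilinear resize → center crop → standardization with the conventional
ImageNet channel statistics) preserves the 448/550 crop ratio at toy
scale (80 → 64).

What the fixtures do **not** model: real photographic content, occlusion,
lighting variation, class imbalance, or label noise. Passing the
desk-scale experiments therefore demonstrates that the mechanisms work as
specified — not that the full-scale accuracy figures transfer.

## Desk-scale study conditions

All experiments run on CPU with the NumPy autodiff core, at sizes chosen
once for this setting:

* smoke training (the main check): 3 classes × 50 images at 64×64,
  60/10/30 split, training noise σ = 0.10, tiny 3-stage backbone with two
  NARMs (D = 16, D″ = 16), batch 16, lr 0.02, up to 30 epochs with early
  stop once the training split is fit;
* robustness trend: 3 classes × 40 images at 32×32, 25 epochs (the
  comparison is meaningful only between near-converged models), 3 seeds,
  ARU+RTU (α, β = 0.6, 0.4) versus an ARU-only control (α, β = 1, 0),
  evaluated at test-time σ ∈ {0, 0.05, 0.10, 0.15, 0.20} with accuracies
  averaged over three independent noise draws per level;
* distillation: the seed-0 dual-branch trend model as teacher, then
  5 paired seeds × (distilled vs no-teacher baseline) students trained
  identically for 24+6 epochs; the distilled arm uses the full procedure
  including per-stage feature alignment (weight 1.0), which is the
  phase-1 mechanism of the method — pure logit distillation is available
  by setting the alignment weight to zero.

The desk-scale learning rate (0.02) differs from the full-scale default
(0.002): tiny networks trained from scratch on ~100 images need the larger
step; `RunConfig` keeps the full-scale values as defaults.

## Known limitations

* The NumPy core is single-threaded and float64; it is built for
  correctness (oracle agreement, finite-difference-verified gradients),
  not throughput. Full-scale (448², ResNet50-width) training is out of
  reach by design; the `resnet50-like` preset is exercised through its
  stride/shape bookkeeping.
* The eigendecomposition VJP assumes simple spectra; regularization makes
  exact degeneracy a measure-zero event, and all pooled quantities are
  basis-independent, but gradients very near degeneracy are ill-
  conditioned.
* The backbone uses plain convolution stages, not residual bottlenecks;
  the preset contract is the stage layout (widths and strides).
* Restoration quality is assessed only by MSE against the clean image;
  no perceptual metrics.
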