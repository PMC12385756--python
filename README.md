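# robustfood

Noise-robust fine-grained food-image recognition: second-order covariance
pooling with eigenvalue enhancement, dual-task (classify + denoise) heads,
multi-granularity fusion with staged training, and temperature-scheduled
knowledge distillation — all runnable at desk scale on procedurally
generated images, with a pure-NumPy differentiable core.

## Who this is for

Researchers and engineers studying noise-robust fine-grained recognition
(food computing, dietary assessment, and similar image-classification
settings) who want a compact, fully inspectable implementation of the
mechanisms — not a GPU training harness. Every operator is differentiable,
oracle-tested, and runs on CPU.

## The model

**EGCP** (eigenvalue-enhanced global covariance pooling). For a feature
map `x ∈ R^{D×H×W}`: standardize each channel (guard ε), form the
precision-weighted channel covariance
`P = (1/N)(W^{1/2} X̃)(W^{1/2} X̃)ᵀ` with `W = diag(1/(σ_d²+ε))`,
regularize `P_reg = P + εI`, eigendecompose `P_reg = U Λ Uᵀ`, floor and
enhance the spectrum `λᵉⁿ = log(1 + λ)`, and rescale by the dynamic factor
`S_F = ‖P_en^{1/2} exp(−P_en)‖_F = √(Σ λᵢᵉⁿ e^{−2λᵢᵉⁿ})`. The descriptor
is `A = (S_F + 1)·P_en^{1/2}`, flattened to `R^{D²}`. The log enhancement
is concave, so small eigenvalues — subtle texture directions — gain
relatively most.

**NARM** (noise-adaptive recognition module). A dual-branch head per
backbone stage: the recognition branch (conv bottleneck → EGCP →
classifier) and a restoration branch (progressive ×2 sub-pixel upsampling
plus a shallow low-level supplement on the noisy input, fused by pixel-wise
addition). Joint loss `L_NARM = α·L_rec + β·L_mse`, default (0.6, 0.4).

**WMF** (weighted multi-granularity fusion). Tapped stage features are
projected, resampled, and fused as `x* = Σ βᵢxᵢ` (default 0.2/0.35/0.45);
training runs S+1 backward passes per batch (each NARM, then the fused
classifier) with one SGD update.

**PTAFD** (progressive temperature-aware feature distillation).
`L = α·L_distill + (1−α)·L_student` with both distributions softened at a
scheduled temperature (0.5 → 2.0), followed by a plain cross-entropy
fine-tuning phase; optional per-stage feature alignment.

See `docs/methods.md` for assumptions, parameter meanings, and the
desk-scale study conditions.

## Worked example

```python
import numpy as np
from robustfood import EGCPConfig, egcp_transform

rng = np.random.default_rng(0)
x = rng.normal(size=(6, 8, 8))            # D=6 channels, 8x8 grid
res = egcp_transform(x, EGCPConfig(epsilon=1e-5))
print(np.round(res.state.lambdas_reg.data, 3))
print(np.round(res.state.lambdas_en.data, 3))
print(round(res.S_F.item(), 4), res.a_flat.data.shape)
```

prints

```
[1.47  1.281 1.1   0.894 0.735 0.673]
[0.904 0.824 0.742 0.639 0.551 0.514]
1.0099 (36,)
```

The first line is the regularized covariance spectrum, the second its
log-enhanced version — the smallest eigenvalue (0.67) retains 76 % of its
value while the largest (1.47) keeps 62 %, the relative amplification of
fine-structure directions. `S_F ≈ 1.01` is the dynamic scaling factor and
the descriptor has length `D² = 36`.

The `examples/` directory walks through each capability end to end
(pooling, fixture generation, staged teacher training, distillation, the
noise sweep, and metrics); each script prints what it computes and what
the numbers mean.

## Command line

```bash
robustfood gen-data --classes 3 --per-class 50 --seed 1 --out data/
robustfood train-teacher --data data/ --epochs 20 --out runs/teacher \
    --config toy.yaml
robustfood distill --data data/ --ckpt runs/teacher/ckpt/teacher.npz \
    --out runs/student --config toy.yaml
robustfood evaluate --data data/ --ckpt runs/teacher/ckpt/teacher.npz \
    --sigma 0.1 --config toy.yaml
robustfood noise-sweep --data data/ --out runs/sweep --config toy.yaml
robustfood denoise-demo --data data/ --ckpt runs/teacher/ckpt/teacher.npz \
    --out runs/panels --config toy.yaml
```

Every run directory receives the exact configuration used, a CSV log and a
`metrics.json`; all randomness flows from `--seed`.

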