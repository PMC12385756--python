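"""Noise Adaptive Recognition Module (NARM).

A NARM is a dual-task head attached to one backbone stage. Both branches
consume the same tapped feature map ``x``:

* **ARU** (Adaptive Recognition Unit) — classification. The Feature
  Transformation Module (FTM: 1x1 conv -> BatchNorm -> ReLU -> 3x3 conv)
  re-projects the stage features, eigenvalue-enhanced covariance pooling
  (:mod:`robustfood.egcp`) turns them into a D^2 second-order descriptor,
  and the Semantic Classification Module (SCM) maps the descriptor to class
  logits. The descriptor has no spatial extent, so the SCM's "1x1
  convolutions" are realized as linear layers.

* **RTU** (Restorative Transformation Unit) — denoising. The Progressive
  Recovery Module (PRM) upsamples the stage features back to image
  resolution through a chain of x2 sub-pixel (pixel-shuffle) modules, each
  ``ReLU(Conv(PixelShuffle(x)))``, halving channels per module, followed by
  a linear 3x3 projection to RGB. The Low-level Feature Supplement (LFS)
  applies two shallow 3x3 convolutions directly to the noisy input image
  (3 -> restore_channels -> 3, no activation). The restored image is their
  pixel-wise sum.

The joint loss is ``L_NARM = alpha * L_rec + beta * L_mse`` where ``L_rec``
is softmax cross-entropy on the logits and ``L_mse`` the mean squared pixel
error of the restoration; ``(alpha, beta) = (0.6, 0.4)`` by default. The
restored image is *not* clamped inside the loss; clamp to [0, 1] only for
display/evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .egcp import EGCPConfig, egcp_transform
from .tensor import Tensor, as_tensor, softmax_cross_entropy

__all__ = [
    "NARMConfig",
    "ImageTriplet",
    "NARMLossBundle",
    "FTM",
    "SCM",
    "PRM",
    "LFS",
    "NARM",
    "narm_loss",
]


@dataclass(frozen=True)
class NARMConfig:
    """Architecture hyperparameters of one NARM.

    ``feature_channels`` (D) is the covariance dimension; ``mid_channels``
    the FTM bottleneck (defaults to D // 2); ``head_hidden`` (D') an optional
    extra hidden width in the SCM classifier; ``restore_channels`` (D'') the
    LFS width; ``upsample_stages`` the number of x2 sub-pixel modules, which
    must satisfy ``stage_size * 2**upsample_stages == target_size``.
    """

    in_channels: int
    feature_channels: int
    num_classes: int
    target_size: tuple[int, int]
    upsample_stages: int
    mid_channels: int | None = None
    head_hidden: int | None = None
    restore_channels: int = 64
    egcp: EGCPConfig = field(default_factory=EGCPConfig)

    def __post_init__(self):
        for name in ("in_channels", "feature_channels", "num_classes",
                     "upsample_stages", "restore_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def mid(self) -> int:
        return self.mid_channels or max(self.feature_channels // 2, 1)


@dataclass
class ImageTriplet:
    """Restoration in/out set, all (B, 3, H', W') in [0, 1] pixel space.

    Invariant: ``I_restored = I_PRM + I_LFS`` exactly (pixel-wise fusion).
    """

    I_noisy: Tensor
    I_PRM: Tensor
    I_LFS: Tensor
    I_restored: Tensor
    I_clean: Tensor | None = None


@dataclass
class NARMLossBundle:
    L_rec: Tensor
    L_mse: Tensor
    alpha: float
    beta: float
    L_NARM: Tensor


class FTM(nn.Module):
    """Feature Transformation Module: 1x1 conv -> BN -> ReLU -> 3x3 conv."""

    def __init__(self, cfg: NARMConfig, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(cfg.in_channels, cfg.mid, 1, rng=rng)
        self.bn = nn.BatchNorm(cfg.mid)
        self.conv2 = nn.Conv2d(cfg.mid, cfg.feature_channels, 3, padding=1, rng=rng)
        self.in_channels = cfg.in_channels

    def forward(self, x):
        if x.data.shape[1] != self.in_channels:
            raise ValueError(f"FTM expects {self.in_channels} input channels, "
                             f"got {x.data.shape[1]}")
        return self.conv2(self.bn(self.conv1(x)).relu())


class SCM(nn.Module):
    """Semantic Classification Module on the flattened covariance descriptor.

    Linear(D^2 -> D) -> BatchNorm -> ReLU, optionally a hidden
    Linear(D -> D') -> ReLU, then the final linear map to N logits.
    """

    def __init__(self, cfg: NARMConfig, rng: np.random.Generator):
        super().__init__()
        D = cfg.feature_channels
        self.d2 = D * D
        self.proj = nn.Linear(self.d2, D, rng=rng)
        self.bn = nn.BatchNorm(D)
        if cfg.head_hidden:
            self.hidden = nn.Linear(D, cfg.head_hidden, rng=rng)
            self.out = nn.Linear(cfg.head_hidden, cfg.num_classes, rng=rng)
        else:
            self.hidden = None
            self.out = nn.Linear(D, cfg.num_classes, rng=rng)

    def forward(self, a_flat):
        if a_flat.data.shape[-1] != self.d2:
            raise ValueError(f"SCM expects descriptors of length {self.d2}, "
                             f"got {a_flat.data.shape[-1]}")
        squeeze = a_flat.data.ndim == 1
        if squeeze:
            a_flat = a_flat.reshape((1, self.d2))
        h = self.bn(self.proj(a_flat)).relu()
        if self.hidden is not None:
            h = self.hidden(h).relu()
        logits = self.out(h)
        return logits.reshape((-1,)) if squeeze else logits


class PRM(nn.Module):
    """Progressive Recovery Module: a chain of x2 sub-pixel upsamplers.

    Each module is ``ReLU(Conv3x3(PixelShuffle2(x)))`` with channels halved
    per module (minimum 4 to keep pixel-shuffle feasible); a final linear
    3x3 convolution projects to RGB.
    """

    def __init__(self, cfg: NARMConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.in_channels   # the RTU consumes the tapped stage feature
        self._stages: list[nn.Module] = []
        for k in range(cfg.upsample_stages):
            if c % 4:
                raise ValueError(
                    f"PRM module {k + 1}: {c} channels not divisible by 4; "
                    "choose stage channels divisible by 2**(upsample_stages+1)")
            out_c = max(c // 2, 4)
            block = nn.Sequential(nn.PixelShuffle(2),
                                  nn.Conv2d(c // 4, out_c, 3, padding=1, rng=rng),
                                  nn.ReLU())
            setattr(self, f"m{k + 1}", block)
            self._stages.append(block)
            c = out_c
        self.proj = nn.Conv2d(c, 3, 3, padding=1, rng=rng)
        # near-zero RGB projection: the recovery chain starts as a small
        # correction on top of the LFS pass-through (identity-oriented
        # initialization, standard for restoration branches)
        self.proj.weight.data *= 1e-2

    def forward(self, x):
        for block in self._stages:
            x = block(x)
        return self.proj(x)


class LFS(nn.Module):
    """Low-level Feature Supplement: two shallow 3x3 convolutions on the
    noisy input (3 -> restore_channels -> 3, no intermediate activation)."""

    def __init__(self, cfg: NARMConfig, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(3, cfg.restore_channels, 3, padding=1, rng=rng)
        self.conv2 = nn.Conv2d(cfg.restore_channels, 3, 3, padding=1, rng=rng)
        # near-identity initialization: delta kernels route each RGB channel
        # through, so the LFS starts as a pass-through and SGD only has to
        # learn the denoising correction
        k = 1  # center of the 3x3 kernel
        self.conv1.weight.data *= 1e-2
        self.conv2.weight.data *= 1e-2
        for c in range(3):
            if c < cfg.restore_channels:
                self.conv1.weight.data[c, c, k, k] += 1.0
                self.conv2.weight.data[c, c, k, k] += 1.0

    def forward(self, i_noisy):
        return self.conv2(self.conv1(i_noisy))


class NARM(nn.Module):
    """One dual-branch head: ARU (FTM -> EGCP -> SCM) and RTU (PRM + LFS)."""

    def __init__(self, cfg: NARMConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.ftm = FTM(cfg, rng)
        self.scm = SCM(cfg, rng)
        self.prm = PRM(cfg, rng)
        self.lfs = LFS(cfg, rng)

    # -- ARU path --------------------------------------------------------------

    def aru_forward(self, x) -> Tensor:
        d2 = self.ftm(x)
        result = egcp_transform(d2, self.cfg.egcp)
        return self.scm(result.a_flat)

    # -- RTU path --------------------------------------------------------------

    def rtu_restore(self, x, i_noisy, i_clean=None) -> ImageTriplet:
        x, i_noisy = as_tensor(x), as_tensor(i_noisy)
        H, W = x.data.shape[-2:]
        factor = 2 ** self.cfg.upsample_stages
        if (H * factor, W * factor) != tuple(self.cfg.target_size):
            raise ValueError(
                f"stage size ({H},{W}) x 2^{self.cfg.upsample_stages} != "
                f"target {self.cfg.target_size}")
        i_prm = self.prm(x)
        i_lfs = self.lfs(i_noisy)
        if i_prm.data.shape != i_lfs.data.shape:
            raise ValueError(f"PRM output {i_prm.data.shape} and LFS output "
                             f"{i_lfs.data.shape} differ in shape")
        return ImageTriplet(I_noisy=i_noisy, I_PRM=i_prm, I_LFS=i_lfs,
                            I_restored=i_prm + i_lfs,
                            I_clean=as_tensor(i_clean) if i_clean is not None else None)

    def forward(self, x, i_noisy, i_clean=None) -> tuple[Tensor, ImageTriplet]:
        x = as_tensor(x)
        return self.aru_forward(x), self.rtu_restore(x, i_noisy, i_clean)


def narm_loss(p, label, i_restored, i_clean,
              alpha: float = 0.6, beta: float = 0.4) -> NARMLossBundle:
    """Joint classification + restoration loss ``alpha*L_rec + beta*L_mse``."""
    p = as_tensor(p)
    i_restored, i_clean = as_tensor(i_restored), as_tensor(i_clean)
    if i_restored.data.shape != i_clean.data.shape:
        raise ValueError("restored and clean images differ in shape")
    l_rec = softmax_cross_entropy(p, label)
    l_mse = ((i_restored - i_clean) ** 2).mean()
    l_narm = alpha * l_rec + beta * l_mse
    return NARMLossBundle(L_rec=l_rec, L_mse=l_mse,
                          alpha=alpha, beta=beta, L_NARM=l_narm)
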