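"""Backbone stage-tapping, weighted multi-granularity fusion, and the
staged (S+1)-loss training procedure.

The teacher network taps ``S`` backbone stages (by default a suffix of the
stage list — "the last stages"), attaches one NARM per tap, and adds a
fusion head: every tapped feature is projected to a common width by a 1x1
convolution, average-resampled to the deepest tap's spatial grid, and
combined as ``x* = sum_i beta_i x_i'`` with fusion weights ``beta``
(default 0.2/0.35/0.45, emphasizing deeper stages). A separate ARU
classifies ``x*``.

One optimization step per batch processes S+1 losses in stage order:
``L_NARM(i) = alpha*L_rec(i) + beta*L_mse(i)`` for each NARM, then the
fused-head cross-entropy. Each loss is backpropagated separately
(gradients accumulate across the S+1 backward passes; a single SGD update
is applied afterwards), so every stage receives direct supervision while
the update itself stays order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .egcp import EGCPConfig, egcp_transform
from .narm import NARM, NARMConfig, narm_loss
from .tensor import Tensor, as_tensor, softmax_cross_entropy

__all__ = [
    "StageSpec",
    "BackboneSpec",
    "FusionConfig",
    "TrainConfig",
    "BACKBONE_PRESETS",
    "backbone_preset",
    "build_backbone",
    "Backbone",
    "FeatureFusion",
    "TeacherModel",
    "fuse_features",
    "wmf_train_step",
    "cosine_lr",
    "train_teacher",
    "evaluate_model",
]


@dataclass(frozen=True)
class StageSpec:
    channels: int
    stride: int = 2


@dataclass(frozen=True)
class BackboneSpec:
    """Preset name, ordered stage descriptors, and which stages feed NARMs."""

    name: str
    stages: tuple[StageSpec, ...]
    taps: tuple[int, ...]

    def __post_init__(self):
        if not self.taps:
            raise ValueError("at least one tapped stage is required")
        if any(t < 0 or t >= len(self.stages) for t in self.taps):
            raise ValueError("tap index out of range")

    @property
    def num_taps(self) -> int:
        return len(self.taps)

    def stage_shapes(self, input_size: tuple[int, int]) -> list[tuple[int, int, int]]:
        """Stride bookkeeping: (channels, H, W) of every stage's output."""
        h, w = input_size
        out = []
        for st in self.stages:
            h, w = h // st.stride, w // st.stride
            out.append((st.channels, h, w))
        return out


BACKBONE_PRESETS: dict[str, BackboneSpec] = {
    # 5-stage layout with ResNet50's stage widths and downsampling factors;
    # taps on the last three stages.
    "resnet50-like": BackboneSpec(
        name="resnet50-like",
        stages=tuple(StageSpec(c) for c in (64, 256, 512, 1024, 2048)),
        taps=(2, 3, 4),
    ),
    # 3-stage desk-scale backbone; taps on the last two stages.
    "tiny": BackboneSpec(
        name="tiny",
        stages=tuple(StageSpec(c) for c in (16, 32, 64)),
        taps=(1, 2),
    ),
}


def backbone_preset(name: str, taps: tuple[int, ...] | None = None) -> BackboneSpec:
    if name not in BACKBONE_PRESETS:
        raise ValueError(f"unknown backbone preset '{name}'; "
                         f"known: {sorted(BACKBONE_PRESETS)}")
    spec = BACKBONE_PRESETS[name]
    return replace(spec, taps=tuple(taps)) if taps is not None else spec


class Backbone(nn.Module):
    """A plain convolutional backbone exposing every stage's output.

    Each stage is conv3x3(stride)+ReLU+conv3x3+ReLU with the preset's
    channel width — the contract is the stage layout (channels and strides),
    not any particular block design.
    """

    def __init__(self, spec: BackboneSpec, rng: np.random.Generator,
                 in_channels: int = 3):
        super().__init__()
        self.spec = spec
        c_in = in_channels
        self._stage_mods: list[nn.Module] = []
        for i, st in enumerate(spec.stages):
            block = nn.Sequential(
                nn.Conv2d(c_in, st.channels, 3, stride=st.stride, padding=1, rng=rng),
                nn.ReLU(),
                nn.Conv2d(st.channels, st.channels, 3, padding=1, rng=rng),
                nn.ReLU(),
            )
            setattr(self, f"stage{i + 1}", block)
            self._stage_mods.append(block)
            c_in = st.channels

    def forward(self, x) -> list[Tensor]:
        feats = []
        for block in self._stage_mods:
            x = block(x)
            feats.append(x)
        return feats

    def tapped(self, feats: list[Tensor]) -> list[Tensor]:
        return [feats[i] for i in self.spec.taps]


def build_backbone(spec: BackboneSpec | str, seed: int = 0,
                   in_channels: int = 3) -> Backbone:
    """Instantiate a backbone from a preset name or spec; seeded, deterministic."""
    if isinstance(spec, str):
        spec = backbone_preset(spec)
    return Backbone(spec, np.random.default_rng(seed), in_channels=in_channels)


@dataclass(frozen=True)
class FusionConfig:
    """Weights and projection width of the multi-granularity fusion."""

    betas: tuple[float, ...] = (0.2, 0.35, 0.45)
    projection_channels: int = 1024
    spatial: str = "deepest"   # resample every tap to the deepest tap's grid

    def __post_init__(self):
        if any(b < 0 for b in self.betas):
            raise ValueError("fusion betas must be nonnegative")
        if self.spatial != "deepest":
            raise ValueError(f"unknown fused spatial policy '{self.spatial}'")


class FeatureFusion(nn.Module):
    """1x1-project each tapped stage to a common width, resample to the
    deepest tap's grid, and sum with weights beta."""

    def __init__(self, fc: FusionConfig, tap_channels: list[int],
                 rng: np.random.Generator):
        super().__init__()
        if len(fc.betas) != len(tap_channels):
            raise ValueError(f"{len(fc.betas)} betas for {len(tap_channels)} taps")
        self.fc = fc
        self._projs: list[nn.Module] = []
        for i, c in enumerate(tap_channels):
            proj = nn.Conv2d(c, fc.projection_channels, 1, rng=rng)
            setattr(self, f"proj{i + 1}", proj)
            self._projs.append(proj)

    def forward(self, feats: list[Tensor]) -> Tensor:
        if len(feats) != len(self._projs):
            raise ValueError(f"expected {len(self._projs)} stage features, "
                             f"got {len(feats)}")
        target = feats[-1].data.shape[-2:]
        fused = None
        for beta, proj, f in zip(self.fc.betas, self._projs, feats):
            g = proj(f)
            if g.data.shape[-2:] != tuple(target):
                g = nn.adaptive_avg_pool2d(g, tuple(target))
            term = beta * g
            fused = term if fused is None else fused + term
        return fused


def fuse_features(feats: list, fusion: FeatureFusion) -> Tensor:
    """Functional wrapper around :class:`FeatureFusion`."""
    return fusion([as_tensor(f) for f in feats])


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (defaults: full-scale protocol)."""

    lr0: float = 0.002
    epochs: int = 200
    batch_size: int = 32
    momentum: float = 0.9
    weight_decay: float = 0.0
    horizon: int | None = None      # cosine horizon; defaults to epochs
    lr_floor: float = 0.0
    seed: int = 0
    alpha: float = 0.6              # classification weight in L_NARM
    beta: float = 0.4               # restoration weight in L_NARM
    max_grad_norm: float | None = 5.0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def cosine_horizon(self) -> int:
        return self.horizon if self.horizon is not None else self.epochs


def cosine_lr(t: float, tc: TrainConfig) -> float:
    """Cosine-annealed learning rate at epoch ``t`` in [0, horizon]."""
    h = tc.cosine_horizon
    if not (0 <= t <= h):
        raise ValueError(f"epoch {t} outside schedule horizon [0, {h}]")
    return tc.lr_floor + 0.5 * (tc.lr0 - tc.lr_floor) * (1.0 + math.cos(math.pi * t / h))


class TeacherModel(nn.Module):
    """Backbone + one NARM per tapped stage + fusion head with its own ARU."""

    def __init__(self, spec: BackboneSpec, num_classes: int,
                 image_size: tuple[int, int],
                 feature_channels: int = 1024,
                 restore_channels: int = 64,
                 head_hidden: int | None = None,
                 fusion: FusionConfig | None = None,
                 egcp: EGCPConfig | None = None,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        egcp = egcp or EGCPConfig()
        self.spec = spec
        self.num_classes = num_classes
        self.image_size = tuple(image_size)
        self.backbone = Backbone(spec, rng)
        shapes = spec.stage_shapes(self.image_size)
        tap_channels = [shapes[i][0] for i in spec.taps]
        self._narms: list[NARM] = []
        for k, i in enumerate(spec.taps):
            c, h, w = shapes[i]
            ups = int(round(math.log2(self.image_size[0] / h)))
            if h * 2 ** ups != self.image_size[0] or w * 2 ** ups != self.image_size[1]:
                raise ValueError(f"stage {i} grid ({h},{w}) cannot be upsampled "
                                 f"by powers of two to {self.image_size}")
            cfg = NARMConfig(in_channels=c, feature_channels=feature_channels,
                             num_classes=num_classes, target_size=self.image_size,
                             upsample_stages=ups, head_hidden=head_hidden,
                             restore_channels=restore_channels, egcp=egcp)
            narm = NARM(cfg, rng)
            setattr(self, f"narm{k + 1}", narm)
            self._narms.append(narm)
        fusion = fusion or FusionConfig(projection_channels=feature_channels)
        self.fusion = FeatureFusion(fusion, tap_channels, rng)
        fused_cfg = NARMConfig(in_channels=fusion.projection_channels,
                               feature_channels=feature_channels,
                               num_classes=num_classes,
                               target_size=self.image_size, upsample_stages=1,
                               head_hidden=head_hidden, egcp=egcp)
        # the fusion head only classifies; reuse the ARU halves of a NARM
        from .narm import FTM, SCM
        self.fused_ftm = FTM(fused_cfg, rng)
        self.fused_scm = SCM(fused_cfg, rng)
        self._egcp_cfg = egcp
        # audit trail of backward passes in the last training step
        self.last_backward_order: list[str] = []

    @property
    def narms(self) -> list[NARM]:
        return self._narms

    @property
    def num_stages(self) -> int:
        return len(self._narms)

    def stage_features(self, images) -> list[Tensor]:
        return self.backbone.tapped(self.backbone(as_tensor(images)))

    def fused_logits_from(self, tapped: list[Tensor]) -> Tensor:
        x_star = self.fusion(tapped)
        d2 = self.fused_ftm(x_star)
        return self.fused_scm(egcp_transform(d2, self._egcp_cfg).a_flat)

    def forward(self, images) -> Tensor:
        """Fused-head logits (the model's primary prediction)."""
        return self.fused_logits_from(self.stage_features(images))

    def stage_logits(self, images) -> list[Tensor]:
        """Per-NARM ARU logits (the p_1..p_S reporting convention)."""
        tapped = self.stage_features(images)
        return [narm.aru_forward(x) for narm, x in zip(self._narms, tapped)]


def wmf_train_step(batch, model: TeacherModel, tc: TrainConfig,
                   opt: nn.SGD) -> list[float]:
    """One S+1-loss training step; returns the S+1 scalar losses in order.

    ``batch = (noisy_images, clean_images, labels)``. The backbone runs
    once; each NARM's joint loss and finally the fused-head cross-entropy
    are backpropagated separately before a single optimizer update.
    """
    noisy, clean, labels = batch
    noisy, clean = as_tensor(noisy), as_tensor(clean)
    opt.zero_grad()
    model.last_backward_order = []
    tapped = model.stage_features(noisy)
    losses: list[float] = []
    for i, (narm, x) in enumerate(zip(model.narms, tapped), start=1):
        if tc.beta == 0:
            # restoration branch carries no training signal; skip its forward
            logits = narm.aru_forward(x)
            bundle = narm_loss(logits, labels, clean, clean,
                               alpha=tc.alpha, beta=tc.beta)
        else:
            logits, triplet = narm(x, noisy, clean)
            bundle = narm_loss(logits, labels, triplet.I_restored, clean,
                               alpha=tc.alpha, beta=tc.beta)
        val = bundle.L_NARM.item()
        if not math.isfinite(val):
            raise RuntimeError(f"non-finite NARM loss at stage {i}: {val}")
        bundle.L_NARM.backward()
        model.last_backward_order.append(f"narm_{i}")
        losses.append(val)
    l_cls = softmax_cross_entropy(model.fused_logits_from(tapped), labels)
    val = l_cls.item()
    if not math.isfinite(val):
        raise RuntimeError(f"non-finite fused classification loss: {val}")
    l_cls.backward()
    model.last_backward_order.append("fusion")
    losses.append(val)
    opt.step()
    return losses


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def evaluate_model(model: TeacherModel, images: np.ndarray, labels: np.ndarray,
                   batch_size: int = 32) -> dict:
    """Fused and per-stage top-1 plus score matrix on a clean split."""
    model.eval()
    n = images.shape[0]
    fused_scores = np.zeros((n, model.num_classes))
    stage_hits = np.zeros(model.num_stages)
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        tapped = model.stage_features(images[sl])
        fused_scores[sl] = model.fused_logits_from(tapped).data
        for k, (narm, x) in enumerate(zip(model.narms, tapped)):
            pred = narm.aru_forward(x).data.argmax(axis=1)
            stage_hits[k] += (pred == labels[sl]).sum()
    model.train()
    top1 = float((fused_scores.argmax(axis=1) == labels).mean())
    k5 = min(5, model.num_classes)
    order = np.argsort(-fused_scores, axis=1, kind="stable")[:, :k5]
    top5 = float((order == labels[:, None]).any(axis=1).mean())
    return {
        "top1": top1,
        "top5": top5,
        "stage_top1": [float(h / n) for h in stage_hits],
        "scores": fused_scores,
    }


def train_teacher(dataset, model: TeacherModel, tc: TrainConfig,
                  noise_sigma: float = 0.10, clip_noise: bool = True,
                  resume: dict | None = None) -> dict:
    """Train a teacher with the staged procedure.

    ``dataset`` is a dict with float arrays ``train_images``/``train_labels``
    and optionally ``val_images``/``val_labels`` (images (n,3,H,W) in [0,1]).
    Gaussian noise of standard deviation ``noise_sigma`` is injected into
    training inputs only; clean images remain the restoration targets.

    ``resume`` accepts the ``resume_state`` of a previous (shorter) run on
    the same schedule; with the model parameters restored, training then
    continues bit-identically to an uninterrupted run. Returns
    ``{"log": [...], "best_state": ..., "best_top1": ..., "resume_state": ...}``.
    """
    train_x = np.asarray(dataset["train_images"], dtype=np.float64)
    train_y = np.asarray(dataset["train_labels"], dtype=np.int64)
    if train_x.shape[0] == 0:
        raise ValueError("empty training split")
    val_x = dataset.get("val_images")
    val_y = dataset.get("val_labels")
    rng = np.random.default_rng(tc.seed)
    opt = nn.SGD(model.parameters(), lr=tc.lr0, momentum=tc.momentum,
                 weight_decay=tc.weight_decay, max_grad_norm=tc.max_grad_norm)
    start_epoch = 0
    if resume is not None:
        start_epoch = resume["epoch"]
        rng.bit_generator.state = resume["rng_state"]
        opt._velocity = [v.copy() for v in resume["velocity"]]
    log: list[dict] = []
    best_top1, best_state = -1.0, None
    for epoch in range(start_epoch, tc.epochs):
        opt.lr = cosine_lr(epoch, tc)
        sums = None
        nb = 0
        for idx in _iter_batches(train_x.shape[0], tc.batch_size, rng):
            clean = train_x[idx]
            noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape) \
                if noise_sigma > 0 else clean.copy()
            if clip_noise and noise_sigma > 0:
                noisy = np.clip(noisy, 0.0, 1.0)
            losses = wmf_train_step((noisy, clean, train_y[idx]), model, tc, opt)
            sums = losses if sums is None else [a + b for a, b in zip(sums, losses)]
            nb += 1
        means = [s / nb for s in sums]
        record = {"epoch": epoch, "lr": opt.lr,
                  **{f"L_NARM_{i + 1}": means[i] for i in range(model.num_stages)},
                  "L_cls": means[-1]}
        ex, ey = (val_x, val_y) if val_x is not None and len(val_x) else (train_x, train_y)
        ev = evaluate_model(model, np.asarray(ex, dtype=np.float64),
                            np.asarray(ey, dtype=np.int64), tc.batch_size)
        record["top1"] = ev["top1"]
        record["top5"] = ev["top5"]
        for k, acc in enumerate(ev["stage_top1"]):
            record[f"p{k + 1}"] = acc
        log.append(record)
        if ev["top1"] >= best_top1:
            best_top1 = ev["top1"]
            best_state = model.state_dict()
    return {"log": log, "best_state": best_state, "best_top1": best_top1,
            "resume_state": {"epoch": tc.epochs,
                             "rng_state": rng.bit_generator.state,
                             "velocity": [v.copy() for v in opt._velocity]}}
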