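"""Progressive Temperature-Aware Feature Distillation (PTAFD).

Transfers the teacher's knowledge (the multi-NARM fused network) into a
plain backbone student. The soft-label loss is the cross-entropy between
teacher and student distributions, both softened at the same temperature T:

    L_distillation = - sum_i softmax(z_t / T)_i * log softmax(z_s / T)_i
    L_student      = cross-entropy of the student at T = 1 against the label
    L_total        = alpha * L_distillation + (1 - alpha) * L_student

No T^2 gradient-compensation factor is applied (deliberately; common KD
practice multiplies the soft term by T^2, the formulation here does not —
see docs/methods.md). The temperature follows a piecewise-linear schedule
over the distillation phase, by default rising from 0.5 (sharp: the
student locks onto the teacher's high-confidence labels) to 2.0 (smooth:
negative-label structure becomes visible); a falling schedule is
selectable. Phase 2 fine-tunes with plain cross-entropy and no teacher.

An optional per-stage feature-alignment term compares teacher and student
stage features after 1x1 projection of the student to the teacher's width
and global L2 normalization (scale-invariant MSE), averaged over stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .tensor import (Tensor, as_tensor, log_softmax, softmax,
                     softmax_cross_entropy, tsum)

__all__ = [
    "DistillConfig",
    "DistillLossBundle",
    "StudentModel",
    "FeatureAligner",
    "soften_logits",
    "distillation_loss",
    "combined_loss",
    "temperature_at",
    "feature_alignment_loss",
    "distill_student",
]


@dataclass(frozen=True)
class DistillConfig:
    alpha: float = 0.5               # weight of the distillation term
    T_start: float = 0.5
    T_end: float = 2.0
    phase_1_epochs: int = 8          # distillation phase
    phase_2_epochs: int = 2          # plain cross-entropy fine-tune
    feature_align_weight: float = 0.0
    schedule: str = "rising"         # or "falling"

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.T_start <= 0 or self.T_end <= 0:
            raise ValueError("temperatures must be positive")
        if self.phase_1_epochs < 0 or self.phase_2_epochs < 0:
            raise ValueError("phase lengths must be >= 0")
        if self.feature_align_weight < 0:
            raise ValueError("feature_align_weight must be >= 0")
        if self.schedule not in ("rising", "falling"):
            raise ValueError("schedule must be 'rising' or 'falling'")


@dataclass
class DistillLossBundle:
    L_distillation: Tensor
    L_student: Tensor
    L_total: Tensor
    alpha: float
    temperature: float


def soften_logits(logits, T: float) -> Tensor:
    """softmax(logits / T): T < 1 sharpens, T > 1 smooths the distribution."""
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return softmax(as_tensor(logits) * (1.0 / T), axis=-1)


def _per_sample_ce(teacher_probs: Tensor, student_log_probs: Tensor) -> Tensor:
    ce = -tsum(teacher_probs * student_log_probs, axis=-1)
    return ce.mean() if ce.data.ndim else ce


def distillation_loss(teacher_logits, student_logits, T: float) -> Tensor:
    """Soft-label cross-entropy with both sides softened at temperature T.

    For batched logits the per-sample class sums are averaged over the batch.
    """
    t, s = as_tensor(teacher_logits), as_tensor(student_logits)
    if t.data.shape != s.data.shape:
        raise ValueError(f"teacher {t.data.shape} and student {s.data.shape} "
                         "logit shapes differ")
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    p_teacher = soften_logits(t.detach(), T)      # teacher never receives grads
    log_p_student = log_softmax(s * (1.0 / T), axis=-1)
    return _per_sample_ce(p_teacher, log_p_student)


def combined_loss(teacher_logits, student_logits, y, dc: DistillConfig,
                  T: float) -> DistillLossBundle:
    """alpha * L_distillation + (1 - alpha) * L_student (student CE at T=1)."""
    l_dist = distillation_loss(teacher_logits, student_logits, T)
    l_student = softmax_cross_entropy(student_logits, y)
    l_total = dc.alpha * l_dist + (1.0 - dc.alpha) * l_student
    return DistillLossBundle(L_distillation=l_dist, L_student=l_student,
                             L_total=l_total, alpha=dc.alpha, temperature=T)


def temperature_at(epoch: int, dc: DistillConfig) -> float:
    """Piecewise-linear temperature schedule; constant 1.0 in phase 2."""
    if epoch >= dc.phase_1_epochs:
        return 1.0
    if dc.phase_1_epochs == 1:
        frac = 1.0
    else:
        frac = min(max(epoch / (dc.phase_1_epochs - 1), 0.0), 1.0)
    lo, hi = dc.T_start, dc.T_end
    if dc.schedule == "falling":
        lo, hi = hi, lo
    return lo + frac * (hi - lo)


def feature_alignment_loss(teacher_stage_feats, student_stage_feats,
                           projections: list[nn.Module] | None = None) -> Tensor:
    """Mean over stages of the MSE between L2-normalized stage features.

    Student features are first 1x1-projected to the teacher's channel width
    when ``projections`` are supplied (required if the widths differ). The
    global L2 normalization makes the distance scale-invariant.
    """
    t_feats = [as_tensor(f) for f in teacher_stage_feats]
    s_feats = [as_tensor(f) for f in student_stage_feats]
    if len(t_feats) != len(s_feats):
        raise ValueError(f"stage count mismatch: teacher {len(t_feats)} "
                         f"vs student {len(s_feats)}")
    total = None
    for k, (tf, sf) in enumerate(zip(t_feats, s_feats)):
        if projections is not None:
            sf = projections[k](sf)
        if tf.data.shape != sf.data.shape:
            raise ValueError(f"stage {k}: teacher {tf.data.shape} vs student "
                             f"{sf.data.shape}; supply 1x1 projections")
        tn = tf * (((tf ** 2).sum()) ** 0.5 + 1e-12) ** -1.0
        sn = sf * (((sf ** 2).sum()) ** 0.5 + 1e-12) ** -1.0
        mse = ((tn - sn) ** 2).mean()
        total = mse if total is None else total + mse
    return total * (1.0 / len(t_feats))


class StudentModel(nn.Module):
    """A plain backbone classifier: global-average-pooled deepest stage
    features followed by a linear head."""

    def __init__(self, spec, num_classes: int, seed: int = 0):
        super().__init__()
        from .training import Backbone
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.num_classes = num_classes
        self.backbone = Backbone(spec, rng)
        self.head = nn.Linear(spec.stages[-1].channels, num_classes, rng=rng)

    def stage_features(self, images) -> list[Tensor]:
        return self.backbone.tapped(self.backbone(as_tensor(images)))

    def forward(self, images):
        feats = self.backbone(as_tensor(images))
        x = feats[-1]
        pooled = x.mean(axis=(-1, -2))
        return self.head(pooled)


class FeatureAligner(nn.Module):
    """1x1 projections mapping student stage widths to teacher widths."""

    def __init__(self, student_channels: list[int], teacher_channels: list[int],
                 rng: np.random.Generator):
        super().__init__()
        self._projs: list[nn.Module] = []
        for i, (sc, tc) in enumerate(zip(student_channels, teacher_channels)):
            proj = nn.Conv2d(sc, tc, 1, rng=rng)
            setattr(self, f"proj{i + 1}", proj)
            self._projs.append(proj)

    @property
    def projections(self) -> list[nn.Module]:
        return self._projs


def distill_student(teacher, student: StudentModel, dataset,
                    dc: DistillConfig, tc) -> dict:
    """Two-phase student training; the teacher is frozen throughout.

    Phase 1 minimizes ``L_total + feature_align_weight * L_feature`` with the
    scheduled temperature; phase 2 trains with plain cross-entropy only.
    Returns ``{"log": [...], "final_state": ...}``.
    """
    if teacher.spec.num_taps != len(student.backbone.spec.taps):
        raise ValueError("teacher and student must share the tapped stage count")
    train_x = np.asarray(dataset["train_images"], dtype=np.float64)
    train_y = np.asarray(dataset["train_labels"], dtype=np.int64)
    if train_x.shape[0] == 0:
        raise ValueError("empty training split")
    rng = np.random.default_rng(tc.seed)
    params = list(student.parameters())
    aligner = None
    if dc.feature_align_weight > 0:
        t_ch = [teacher.spec.stages[i].channels for i in teacher.spec.taps]
        s_ch = [student.backbone.spec.stages[i].channels
                for i in student.backbone.spec.taps]
        aligner = FeatureAligner(s_ch, t_ch, np.random.default_rng(tc.seed + 1))
        params += aligner.parameters()
    opt = nn.SGD(params, lr=tc.lr0, momentum=tc.momentum,
                 weight_decay=tc.weight_decay,
                 max_grad_norm=getattr(tc, "max_grad_norm", None))
    teacher.eval()
    total_epochs = dc.phase_1_epochs + dc.phase_2_epochs
    log: list[dict] = []
    from .training import _iter_batches, cosine_lr, TrainConfig
    sched = TrainConfig(lr0=tc.lr0, epochs=max(total_epochs, 1),
                        batch_size=tc.batch_size, momentum=tc.momentum,
                        seed=tc.seed)
    # the teacher is frozen and deterministic in eval mode, so its logits
    # and stage features over the training set can be computed once
    cached_logits = None
    cached_feats = None
    if dc.phase_1_epochs > 0 and (dc.alpha > 0 or dc.feature_align_weight > 0):
        outs, feats = [], None
        for start in range(0, train_x.shape[0], tc.batch_size):
            sl = slice(start, start + tc.batch_size)
            tapped = teacher.stage_features(train_x[sl])
            outs.append(teacher.fused_logits_from(tapped).data.copy())
            if dc.feature_align_weight > 0:
                if feats is None:
                    feats = [[] for _ in tapped]
                for k, f in enumerate(tapped):
                    feats[k].append(f.data.copy())
        if dc.alpha > 0:
            cached_logits = np.concatenate(outs, axis=0)
        if dc.feature_align_weight > 0:
            cached_feats = [np.concatenate(chunks, axis=0) for chunks in feats]
    for epoch in range(total_epochs):
        phase = 1 if epoch < dc.phase_1_epochs else 2
        T = temperature_at(epoch, dc)
        opt.lr = cosine_lr(epoch, sched)
        loss_sum, nb = 0.0, 0
        for idx in _iter_batches(train_x.shape[0], tc.batch_size, rng):
            x, y = train_x[idx], train_y[idx]
            opt.zero_grad()
            if phase == 1 and (dc.alpha > 0 or dc.feature_align_weight > 0):
                s_logits = student(x)
                if dc.alpha > 0:
                    t_logits = cached_logits[idx]
                    bundle = combined_loss(t_logits, s_logits, y, dc, T)
                    loss = bundle.L_total
                else:
                    loss = softmax_cross_entropy(s_logits, y)
                if dc.feature_align_weight > 0:
                    t_feats = [Tensor(f[idx]) for f in cached_feats]
                    loss = loss + dc.feature_align_weight * feature_alignment_loss(
                        t_feats, student.stage_features(x),
                        aligner.projections)
            else:
                loss = softmax_cross_entropy(student(x), y)
            loss.backward()
            opt.step()
            loss_sum += loss.item()
            nb += 1
        record = {"epoch": epoch, "phase": phase, "T": T, "lr": opt.lr,
                  "loss": loss_sum / nb}
        log.append(record)
    return {"log": log, "final_state": student.state_dict()}
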