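"""High-level runs: build models from a :class:`RunConfig`, train, evaluate,
sweep noise levels, and render denoising panels. The CLI and the example
scripts are thin wrappers over these functions."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .checkpoint import Checkpoint, load_checkpoint, load_into_model, save_checkpoint
from .config import RunConfig
from .data import (DatasetManifest, NoiseSpec,
                   inject_gaussian_noise, load_split, noise_sweep_manifest)
from .egcp import EGCPConfig
from .metrics import EvalRecord, per_class_scores, top_k_accuracy
from .ptafd import DistillConfig, StudentModel, distill_student
from .training import (FusionConfig, TeacherModel, TrainConfig, backbone_preset,
                       evaluate_model, train_teacher)

__all__ = [
    "fusion_betas_for",
    "dataset_arrays",
    "build_teacher",
    "build_student",
    "teacher_training_run",
    "evaluate_scores",
    "evaluate_teacher",
    "distillation_run",
    "noise_sweep_run",
    "denoise_panels",
]


def fusion_betas_for(betas: tuple[float, ...], num_taps: int) -> tuple[float, ...]:
    """Adapt fusion weights to the tapped stage count.

    An exact-length vector is used as given. When fewer taps exist than
    weights, the deepest ``num_taps`` weights are kept and renormalized to
    sum to 1, preserving the increasing emphasis on deeper stages.
    """
    if len(betas) == num_taps:
        return tuple(betas)
    if len(betas) > num_taps:
        tail = betas[-num_taps:]
        s = sum(tail)
        return tuple(b / s for b in tail)
    raise ValueError(f"{len(betas)} fusion weights for {num_taps} taps")


def dataset_arrays(manifest: DatasetManifest) -> dict:
    """Load all splits into float arrays keyed <split>_images/<split>_labels."""
    out = {}
    for split in ("train", "val", "test"):
        try:
            x, y = load_split(manifest, split)
        except ValueError:
            continue
        out[f"{split}_images"] = x
        out[f"{split}_labels"] = y
    return out


def build_teacher(cfg: RunConfig, num_classes: int, image_size: int,
                  seed: int = 0) -> TeacherModel:
    spec = backbone_preset(cfg.model.backbone)
    betas = fusion_betas_for(cfg.fusion.betas, spec.num_taps)
    proj = cfg.fusion.projection_channels or cfg.model.feature_channels
    model = TeacherModel(
        spec, num_classes=num_classes, image_size=(image_size, image_size),
        feature_channels=cfg.model.feature_channels,
        restore_channels=cfg.model.restore_channels,
        head_hidden=cfg.model.head_hidden or None,
        fusion=FusionConfig(betas=betas, projection_channels=proj),
        egcp=EGCPConfig(epsilon=cfg.model.epsilon),
        seed=seed)
    return model


def build_student(cfg: RunConfig, num_classes: int, seed: int = 0) -> StudentModel:
    return StudentModel(backbone_preset(cfg.model.backbone), num_classes, seed=seed)


def train_config(cfg: RunConfig, seed: int | None = None,
                 epochs: int | None = None) -> TrainConfig:
    t = cfg.training
    return TrainConfig(lr0=t.lr0, epochs=epochs or t.epochs,
                       batch_size=t.batch_size, momentum=t.momentum,
                       weight_decay=t.weight_decay, alpha=t.alpha, beta=t.beta,
                       seed=t.seed if seed is None else seed)


def teacher_training_run(cfg: RunConfig, manifest: DatasetManifest,
                         seed: int | None = None, epochs: int | None = None,
                         sigma: float | None = None) -> tuple[TeacherModel, dict]:
    data = dataset_arrays(manifest)
    tc = train_config(cfg, seed=seed, epochs=epochs)
    model = build_teacher(cfg, len(manifest.classes), manifest.image_size,
                          seed=tc.seed)
    result = train_teacher(data, model, tc,
                           noise_sigma=cfg.noise.sigma if sigma is None else sigma,
                           clip_noise=cfg.noise.clip)
    return model, result


def evaluate_scores(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Top-1 / top-k and macro-F1 from a score matrix."""
    rec = EvalRecord.from_scores(labels, scores)
    n_classes = scores.shape[1]
    k5 = min(5, n_classes)
    table = per_class_scores(rec, n_classes=n_classes)
    return {"top1": top_k_accuracy(rec, 1),
            "top5": top_k_accuracy(rec, k5),
            "macro_f1": table.macro_f1,
            "per_class": table.rows()}


def evaluate_teacher(model: TeacherModel, images: np.ndarray,
                     labels: np.ndarray, sigma: float = 0.0,
                     noise_seed: int = 0) -> dict:
    if sigma > 0:
        ns = NoiseSpec(sigma=sigma, seed=noise_seed)
        images = np.stack([inject_gaussian_noise(im, ns, index=i)
                           for i, im in enumerate(images)])
    ev = evaluate_model(model, images, labels)
    out = evaluate_scores(ev["scores"], labels)
    out["stage_top1"] = ev["stage_top1"]
    return out


def distillation_run(cfg: RunConfig, teacher: TeacherModel,
                     manifest: DatasetManifest, seed: int | None = None,
                     dc: DistillConfig | None = None) -> tuple[StudentModel, dict]:
    data = dataset_arrays(manifest)
    tc = train_config(cfg, seed=seed)
    dc = dc or DistillConfig(alpha=cfg.distill.alpha, T_start=cfg.distill.T_start,
                             T_end=cfg.distill.T_end,
                             phase_1_epochs=cfg.distill.phase_1_epochs,
                             phase_2_epochs=cfg.distill.phase_2_epochs,
                             feature_align_weight=cfg.distill.feature_align_weight,
                             schedule=cfg.distill.schedule)
    student = build_student(cfg, len(manifest.classes), seed=tc.seed)
    result = distill_student(teacher, student, data, dc, tc)
    return student, result


def noise_sweep_run(cfg: RunConfig, manifest: DatasetManifest, sigmas,
                    epochs: int | None = None, seed: int = 0) -> list[dict]:
    """Train one teacher per training-noise level; evaluate on the shared
    clean test split."""
    variants = noise_sweep_manifest(manifest, sigmas, seed=seed)
    data = dataset_arrays(manifest)
    test_x, test_y = data["test_images"], data["test_labels"]
    rows = []
    for var in variants:
        model, result = teacher_training_run(cfg, manifest, seed=seed,
                                             epochs=epochs, sigma=var.sigma)
        ev = evaluate_teacher(model, test_x, test_y)
        rows.append({"sigma": var.sigma, "test_top1": ev["top1"],
                     "test_top5": ev["top5"], "macro_f1": ev["macro_f1"],
                     "best_val_top1": result["best_top1"]})
    return rows


def restoration_mse(model: TeacherModel, images: np.ndarray, sigma: float,
                    noise_seed: int = 0) -> dict:
    """Held-out restoration quality: MSE(restored, clean) per NARM vs the
    noisy baseline MSE(noisy, clean)."""
    ns = NoiseSpec(sigma=sigma, seed=noise_seed, clip=True)
    noisy = np.stack([inject_gaussian_noise(im, ns, index=i)
                      for i, im in enumerate(images)])
    model.eval()
    tapped = model.stage_features(noisy)
    out = {"noisy_mse": float(np.mean((noisy - images) ** 2)), "restored_mse": []}
    for narm, x in zip(model.narms, tapped):
        trip = narm.rtu_restore(x, noisy)
        restored = np.clip(trip.I_restored.data, 0.0, 1.0)
        out["restored_mse"].append(float(np.mean((restored - images) ** 2)))
    model.train()
    return out


def denoise_panels(model: TeacherModel, images: np.ndarray, sigma: float,
                   out_dir: str | Path, noise_seed: int = 0,
                   max_images: int = 4) -> list[Path]:
    """Write side-by-side noisy | clean | restored-per-NARM panels as PNGs."""
    from PIL import Image
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = images[:max_images]
    ns = NoiseSpec(sigma=sigma, seed=noise_seed, clip=True)
    noisy = np.stack([inject_gaussian_noise(im, ns, index=i)
                      for i, im in enumerate(images)])
    model.eval()
    tapped = model.stage_features(noisy)
    restored = [np.clip(narm.rtu_restore(x, noisy).I_restored.data, 0, 1)
                for narm, x in zip(model.narms, tapped)]
    model.train()
    paths = []
    for i in range(images.shape[0]):
        cols = [noisy[i], images[i]] + [r[i] for r in restored]
        panel = np.concatenate(cols, axis=2)        # side by side
        arr = (panel * 255).round().astype(np.uint8).transpose(1, 2, 0)
        p = out_dir / f"denoise_{i}.png"
        Image.fromarray(arr, mode="RGB").save(p)
        paths.append(p)
    return paths


def save_teacher_checkpoint(model: TeacherModel, cfg: RunConfig, path,
                            epoch: int = 0, history: list | None = None) -> None:
    save_checkpoint(Checkpoint(state=model.state_dict(), config=cfg.to_dict(),
                               epoch=epoch, history=history or []), path)


def load_teacher_checkpoint(path, cfg: RunConfig, num_classes: int,
                            image_size: int, seed: int = 0) -> TeacherModel:
    ckpt = load_checkpoint(path)
    model = build_teacher(cfg, num_classes, image_size, seed=seed)
    load_into_model(ckpt, model)
    return model
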