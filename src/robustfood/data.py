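"""Synthetic "toy food" image fixtures, Gaussian noise injection, and the
resize/crop/normalize preprocessing pipeline.

The generator emulates the two difficulties of fine-grained food
recognition at desk scale: *inter-class similarity* (all classes draw from
overlapping warm color palettes, so color alone is weakly informative) and
*intra-class variability* (per-image jitter of texture scale, orientation,
brightness, and palette). Each class is a procedural recipe — a base color
plus one of three texture families (blobs / stripes / granules) with
class-specific parameters — so classes differ mainly in their texture
statistics, the signal second-order pooling is designed to capture.

Noise injection follows the training-only protocol: zero-mean Gaussian
noise, independent per pixel and per RGB channel, on the [0, 1] pixel scale,
with a fixed seed for reproducibility; test images stay clean.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "DatasetManifest",
    "ManifestEntry",
    "NoiseSpec",
    "PreprocessSpec",
    "TrainingVariant",
    "generate_toy_dataset",
    "inject_gaussian_noise",
    "load_split",
    "noise_sweep_manifest",
    "preprocess",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

_TEXTURES = ("blobs", "stripes", "granules")


@dataclass
class ManifestEntry:
    path: str
    class_index: int
    split: str


@dataclass
class DatasetManifest:
    """Class names, file paths, split labels and the generating seed."""

    classes: list[str]
    entries: list[ManifestEntry]
    seed: int
    image_size: int
    root: str

    def paths(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]

    def to_json(self, path: str | Path) -> None:
        payload = {"classes": self.classes, "seed": self.seed,
                   "image_size": self.image_size, "root": self.root,
                   "entries": [asdict(e) for e in self.entries]}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        return cls(classes=d["classes"],
                   entries=[ManifestEntry(**e) for e in d["entries"]],
                   seed=d["seed"], image_size=d["image_size"], root=d["root"])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for e in sorted(self.entries, key=lambda e: e.path):
            h.update(Path(self.root, e.path).read_bytes())
        return h.hexdigest()


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian pixel noise on the [0, 1] scale."""

    sigma: float
    seed: int = 0
    clip: bool = True
    train_only: bool = True

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class PreprocessSpec:
    """Resize -> center-crop -> [0,1] -> channel standardization."""

    resize_to: int = 550
    crop_to: int = 448
    mean: tuple[float, float, float] = IMAGENET_MEAN
    std: tuple[float, float, float] = IMAGENET_STD

    def __post_init__(self):
        if self.crop_to > self.resize_to:
            raise ValueError("crop_to must be <= resize_to")


@dataclass(frozen=True)
class TrainingVariant:
    """One training condition of a noise sweep (clean shared test split)."""

    sigma: float
    noise: NoiseSpec
    manifest: DatasetManifest


# -- procedural texture rendering ----------------------------------------------

# warm, overlapping palette: classes are NOT separable by mean color alone
_PALETTE = np.array([
    (0.78, 0.55, 0.35), (0.72, 0.60, 0.38), (0.80, 0.50, 0.42),
    (0.70, 0.52, 0.30), (0.76, 0.62, 0.44), (0.68, 0.48, 0.36),
    (0.82, 0.58, 0.40), (0.74, 0.46, 0.32),
])


def _smooth(img: np.ndarray, passes: int) -> np.ndarray:
    """Cheap separable box blur with edge wrap (keeps textures stationary)."""
    for _ in range(passes):
        img = (img + np.roll(img, 1, 0) + np.roll(img, -1, 0)
               + np.roll(img, 1, 1) + np.roll(img, -1, 1)) / 5.0
    return img


def _render_pattern(family: str, size: int, rng: np.random.Generator,
                    scale: float, angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / size
    if family == "stripes":
        u = xx * np.cos(angle) + yy * np.sin(angle)
        phase = rng.uniform(0, 2 * np.pi)
        pat = 0.5 + 0.5 * np.sin(2 * np.pi * scale * u + phase)
    elif family == "blobs":
        k = max(2, int(round(scale)))
        low = rng.random((k, k))
        rep = int(np.ceil(size / k))
        pat = np.kron(low, np.ones((rep, rep)))[:size, :size]
        pat = _smooth(pat, passes=4)
        pat = 1.0 / (1.0 + np.exp(-8.0 * (pat - pat.mean())))
    elif family == "granules":
        density = min(max(scale / 40.0, 0.02), 0.6)
        pat = (rng.random((size, size)) < density).astype(np.float64)
        pat = _smooth(pat, passes=1)
        pat = pat / max(pat.max(), 1e-9)
    else:  # pragma: no cover - guarded by _TEXTURES
        raise ValueError(f"unknown texture family '{family}'")
    return pat


def _class_recipe(class_index: int, rng: np.random.Generator) -> dict:
    family = _TEXTURES[class_index % len(_TEXTURES)]
    base_scales = {"stripes": rng.uniform(4.0, 9.0),
                   "blobs": rng.uniform(4.0, 8.0),
                   "granules": rng.uniform(6.0, 18.0)}
    return {
        "family": family,
        "color": _PALETTE[class_index % len(_PALETTE)],
        "scale": base_scales[family],
        "angle": rng.uniform(0, np.pi),
    }


def _render_image(recipe: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    # per-image jitter: scale, rotation, brightness, palette shift
    scale = recipe["scale"] * rng.uniform(0.85, 1.15)
    angle = recipe["angle"] + rng.normal(0.0, 0.15)
    pat = _render_pattern(recipe["family"], size, rng, scale, angle)
    color = np.clip(recipe["color"] + rng.normal(0.0, 0.04, size=3), 0.05, 0.95)
    brightness = rng.uniform(0.85, 1.1)
    img = color[:, None, None] * (0.55 + 0.45 * pat[None, :, :]) * brightness
    img = img + rng.normal(0.0, 0.01, size=img.shape)   # mild sensor texture
    return np.clip(img, 0.0, 1.0)


def _split_counts(per_class: int, ratios: tuple[float, ...]) -> list[int]:
    counts = [int(round(per_class * r)) for r in ratios]
    counts[-1] = per_class - sum(counts[:-1])
    if any(c < 1 for c in counts):
        raise ValueError(
            f"per_class={per_class} too small for split ratios {ratios}; "
            "every split needs at least one image per class")
    return counts


def generate_toy_dataset(n_classes: int, per_class: int, out_dir: str | Path,
                         image_size: int = 64, seed: int = 0,
                         split_ratios: tuple[float, float, float] = (0.6, 0.1, 0.3),
                         ) -> DatasetManifest:
    """Write a procedurally generated labeled image set as PNGs.

    Layout: one directory per class under ``out_dir``; splits are stratified
    per class at ``split_ratios`` (default 60/10/30). The whole dataset is a
    pure function of ``seed`` (byte-identical files on regeneration).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if per_class < 6:
        raise ValueError("need at least 6 images per class")
    counts = _split_counts(per_class, split_ratios)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(seed)
    class_seqs = root_seq.spawn(n_classes)
    classes = [f"class_{c:02d}" for c in range(n_classes)]
    entries: list[ManifestEntry] = []
    split_names = ("train", "val", "test")
    for c, cname in enumerate(classes):
        (out_dir / cname).mkdir(exist_ok=True)
        crng = np.random.default_rng(class_seqs[c])
        recipe = _class_recipe(c, crng)
        img_seqs = class_seqs[c].spawn(per_class + 1)  # [0] consumed by recipe rng
        order = crng.permutation(per_class)
        split_of = np.empty(per_class, dtype=object)
        pos = 0
        for sname, cnt in zip(split_names, counts):
            split_of[order[pos:pos + cnt]] = sname
            pos += cnt
        for i in range(per_class):
            irng = np.random.default_rng(img_seqs[i + 1])
            img = _render_image(recipe, image_size, irng)
            arr = (np.round(img * 255.0)).astype(np.uint8).transpose(1, 2, 0)
            rel = f"{cname}/img_{i:04d}.png"
            Image.fromarray(arr, mode="RGB").save(out_dir / rel)
            entries.append(ManifestEntry(path=rel, class_index=c,
                                         split=str(split_of[i])))
    manifest = DatasetManifest(classes=classes, entries=entries, seed=seed,
                               image_size=image_size, root=str(out_dir))
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def load_split(manifest: DatasetManifest, split: str
               ) -> tuple[np.ndarray, np.ndarray]:
    """Load a split as float images (n, 3, H, W) in [0, 1] plus labels."""
    entries = manifest.paths(split)
    if not entries:
        raise ValueError(f"split '{split}' is empty")
    images = np.stack([
        np.asarray(Image.open(Path(manifest.root, e.path)).convert("RGB"),
                   dtype=np.float64).transpose(2, 0, 1) / 255.0
        for e in entries])
    labels = np.array([e.class_index for e in entries], dtype=np.int64)
    return images, labels


def inject_gaussian_noise(image: np.ndarray, ns: NoiseSpec,
                          index: int = 0) -> np.ndarray:
    """Add N(0, sigma^2) noise per pixel per channel; deterministic under
    (spec seed, image index); clips to [0, 1] when ``ns.clip``."""
    image = np.asarray(image, dtype=np.float64)
    if ns.sigma == 0:
        return image.copy()
    rng = np.random.default_rng(np.random.SeedSequence((ns.seed, index)))
    noisy = image + rng.normal(0.0, ns.sigma, size=image.shape)
    return np.clip(noisy, 0.0, 1.0) if ns.clip else noisy


def preprocess(image, ps: PreprocessSpec = PreprocessSpec()) -> np.ndarray:
    """Bilinear resize, center crop, scale to [0,1], standardize per channel.

    Accepts a PIL image or an (H, W, 3) / (3, H, W) array; returns a float
    (3, crop, crop) array.
    """
    if isinstance(image, np.ndarray):
        arr = image
        if arr.ndim == 3 and arr.shape[0] == 3:
            arr = arr.transpose(1, 2, 0)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("expected an RGB image")
        if arr.dtype != np.uint8:
            arr = (np.clip(arr, 0.0, 1.0) * 255.0).round().astype(np.uint8)
        pil = Image.fromarray(arr, mode="RGB")
    else:
        pil = image
        if pil.mode != "RGB":
            raise ValueError(f"expected an RGB image, got mode '{pil.mode}'")
    pil = pil.resize((ps.resize_to, ps.resize_to), Image.BILINEAR)
    off = (ps.resize_to - ps.crop_to) // 2
    pil = pil.crop((off, off, off + ps.crop_to, off + ps.crop_to))
    x = np.asarray(pil, dtype=np.float64).transpose(2, 0, 1) / 255.0
    mean = np.asarray(ps.mean).reshape(3, 1, 1)
    std = np.asarray(ps.std).reshape(3, 1, 1)
    return (x - mean) / std


def noise_sweep_manifest(base: DatasetManifest, sigmas,
                         seed: int = 0) -> list[TrainingVariant]:
    """One training variant per sigma; the clean test split is shared."""
    sigmas = list(sigmas)
    if not sigmas:
        raise ValueError("sigmas must be non-empty")
    if len(set(sigmas)) != len(sigmas):
        raise ValueError("duplicate sigma values in noise sweep")
    return [TrainingVariant(sigma=float(s),
                            noise=NoiseSpec(sigma=float(s), seed=seed),
                            manifest=base)
            for s in sigmas]
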