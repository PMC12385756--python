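"""Checkpoint I/O: lossless round-trips of parameters, configuration, RNG
state and metric history, with an architecture fingerprint check on load."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Checkpoint", "save_checkpoint", "load_checkpoint", "load_into_model"]

_META_KEY = "__meta__"


@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    config: dict = field(default_factory=dict)
    epoch: int = 0
    rng_state: dict | None = None
    history: list = field(default_factory=list)

    def fingerprint(self) -> dict[str, tuple[int, ...]]:
        return {k: tuple(v.shape) for k, v in self.state.items()}


def _norm(path: str | Path) -> Path:
    path = Path(path)
    return path if path.suffix == ".npz" else path.with_name(path.name + ".npz")


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    path = _norm(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"config": ckpt.config, "epoch": ckpt.epoch,
                       "rng_state": ckpt.rng_state, "history": ckpt.history})
    arrays = {k: np.ascontiguousarray(v) for k, v in ckpt.state.items()}
    np.savez(path, **arrays, **{_META_KEY: np.frombuffer(meta.encode(), dtype=np.uint8)})


def load_checkpoint(path: str | Path) -> Checkpoint:
    path = _norm(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        meta = json.loads(bytes(data[_META_KEY]).decode())
        state = {k: data[k] for k in data.files if k != _META_KEY}
    return Checkpoint(state=state, config=meta["config"], epoch=meta["epoch"],
                      rng_state=meta["rng_state"], history=meta["history"])


def load_into_model(ckpt: Checkpoint, model) -> None:
    """Load parameters into a model, refusing on architecture mismatch with a
    diff of the offending shapes."""
    want = {name: tuple(p.data.shape) for name, p in model.named_parameters()}
    for name, arr in model.named_buffers():
        want[name] = tuple(arr.shape)
    have = ckpt.fingerprint()
    diffs = []
    for name in sorted(set(want) | set(have)):
        w, h = want.get(name), have.get(name)
        if w != h:
            diffs.append(f"  {name}: model={w} checkpoint={h}")
    if diffs:
        raise ValueError("architecture fingerprint mismatch:\n" + "\n".join(diffs))
    model.load_state_dict(ckpt.state)
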