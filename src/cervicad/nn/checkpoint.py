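"""Checkpointing: parameters as .npz plus a JSON sidecar with the model
config and the training seed, so every checkpoint is reproducible."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np


def _param_dict(model) -> dict[str, np.ndarray]:
    return {f"p{i}": p.value for i, p in enumerate(model.params())}


def clone_params(model) -> list[np.ndarray]:
    return [p.value.copy() for p in model.params()]


def set_params(model, values) -> None:
    for p, v in zip(model.params(), values, strict=True):
        p.value[...] = v


def model_digest(model) -> str:
    """SHA-256 over the concatenated parameter bytes."""
    h = hashlib.sha256()
    for p in model.params():
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()


def save_model(path, model, kind: str, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **_param_dict(model))
    sidecar = {"kind": kind, "config": model.config(), "meta": copy.deepcopy(meta or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path):
    from .cnn import MicroCNN
    from .unet import UNet

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = sidecar["config"]
    if sidecar["kind"] == "unet":
        model = UNet(**cfg)
    elif sidecar["kind"] == "microcnn":
        cfg = dict(cfg)
        cfg["widths"] = tuple(cfg["widths"])
        model = MicroCNN(**cfg)
    else:
        raise ValueError(f"unknown checkpoint kind {sidecar['kind']!r}")
    data = np.load(path.with_suffix(".npz"))
    set_params(model, [data[f"p{i}"] for i in range(len(model.params()))])
    return model, sidecar
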