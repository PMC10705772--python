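"""Model checkpointing.

A checkpoint is a single ``.npz`` archive holding every parameter array in
construction order plus the JSON-encoded experiment configuration, so
loading rebuilds the exact model (the parameter ordering is deterministic
given the config).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import ExperimentConfig, build_model, config_to_dict, load_config
from .model import YolactModel


def save_checkpoint(model: YolactModel, cfg: ExperimentConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i:05d}": p.data for i, p in enumerate(model.parameters())}
    arrays["__config__"] = np.frombuffer(
        json.dumps(config_to_dict(cfg)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[YolactModel, ExperimentConfig]:
    with np.load(path) as z:
        cfg_json = bytes(z["__config__"]).decode()
        cfg = load_config(json.loads(cfg_json))
        model = build_model(cfg)
        params = model.parameters()
        keys = sorted(k for k in z.files if k.startswith("param_"))
        if len(keys) != len(params):
            raise ValueError(f"checkpoint has {len(keys)} parameter arrays, "
                             f"model expects {len(params)}")
        for k, p in zip(keys, params):
            arr = z[k]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs "
                                 f"{p.data.shape}")
            p.data = arr.astype(p.data.dtype)
    return model, cfg
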