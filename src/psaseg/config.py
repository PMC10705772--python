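"""Declarative experiment configuration.

One YAML file (or nested dict) describes the whole experiment: backbone
and pyramid, detector hyperparameters, training recipe, augmentation
probabilities, synthetic-data settings, and evaluation thresholds.  All
defaults encode the full-scale setup (SGD lr 0.001 / momentum 0.9 / weight
decay 5e-4, batch 8, the standard channel normalization constants, anchor
IoU thresholds 0.5/0.4, test score threshold 0.05), so an empty file is a
valid experiment.  Unknown keys are rejected with the offending path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .augment import AugmentationSpec
from .backbone import BackboneConfig
from .model import ModelConfig, YolactModel
from .synth import NightParams, SynthConfig
from .train import TrainConfig


@dataclass
class DataConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_scenes: int = 16
    split_fractions: tuple = (0.5, 0.25, 0.25)
    dir: str | None = None     # use a pre-generated dataset instead of synth


@dataclass
class EvalConfig:
    score_threshold: float = 0.05
    nms_iou: float = 0.5
    mask_threshold: float = 0.5


@dataclass
class ExperimentConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    augment: bool = False
    data: DataConfig = field(default_factory=DataConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0


class ConfigError(ValueError):
    pass


def _build(cls, payload, path=""):
    if payload is None:
        return cls()
    if not isinstance(payload, dict):
        raise ConfigError(f"expected a mapping at {path or 'top level'}, "
                          f"got {type(payload).__name__}")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, val in payload.items():
        if key not in known:
            raise ConfigError(f"unknown configuration key {path + key!r}")
        ftype = known[key].type
        default = known[key].default_factory() if known[key].default_factory \
            is not dataclasses.MISSING else known[key].default
        if is_dataclass(default) or (isinstance(ftype, type) and is_dataclass(ftype)):
            cls2 = type(default) if is_dataclass(default) else ftype
            kwargs[key] = _build(cls2, val, path=f"{path}{key}.")
        elif isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def load_config(path_or_dict) -> ExperimentConfig:
    """Load and validate an experiment configuration."""
    if isinstance(path_or_dict, ExperimentConfig):
        return path_or_dict
    if isinstance(path_or_dict, dict) or path_or_dict is None:
        payload = path_or_dict
    else:
        with open(path_or_dict) as fh:
            payload = yaml.safe_load(fh)
    return _build(ExperimentConfig, payload)


def config_to_dict(cfg) -> dict:
    if is_dataclass(cfg):
        return {f.name: config_to_dict(getattr(cfg, f.name)) for f in fields(cfg)}
    if isinstance(cfg, tuple):
        return [config_to_dict(v) for v in cfg]
    if isinstance(cfg, Path):
        return str(cfg)
    return cfg


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def build_model(cfg: ExperimentConfig) -> YolactModel:
    """Construct the (seeded) detector described by a configuration."""
    model_cfg = dataclasses.replace(
        cfg.model,
        score_threshold=cfg.eval.score_threshold,
        nms_iou=cfg.eval.nms_iou,
        mask_threshold=cfg.eval.mask_threshold,
    )
    return YolactModel(cfg.backbone, model_cfg, seed=cfg.seed)


# ---------------------------------------------------------------------------
# Desk-scale presets
# ---------------------------------------------------------------------------

def tiny_experiment(attention: str = "psa", seed: int = 0,
                    epochs: int = 200, lr: float = 0.02) -> ExperimentConfig:
    """The desk-scale setup: tiny backbone, 64x128 scenes, scaled anchors."""
    return ExperimentConfig(
        backbone=BackboneConfig(variant="tiny", fpn_channels=64,
                                attention=attention, seed=seed),
        model=ModelConfig(k=8, anchor_scales=(6, 12, 24, 48, 96),
                          head_channels=32),
        train=TrainConfig(epochs=epochs, lr=lr, warmup_steps=20, seed=seed),
        data=DataConfig(synth=SynthConfig(image_size=(64, 128),
                                          instance_range=(1, 3),
                                          blob_radius_range=(9, 16),
                                          seed=seed),
                        n_scenes=8, split_fractions=(1.0,)),
        seed=seed,
    )
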