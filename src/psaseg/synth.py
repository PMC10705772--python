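"""Seeded generator of multi-instance animal-blob scenes with COCO ground truth.

Scenes emulate the statistical hard cases of group-housed livestock imagery
without attempting photorealism: several overlapping elongated blobs
(ellipse unions standing in for bodies with heads) on a textured pen-like
background, composited back-to-front so later bodies occlude earlier ones,
optionally barred by fence-like occluders, with day and night variants
(night = brightness collapse + desaturation + sensor noise).  Ground truth
records the *visible* part of each instance, matching COCO annotation
practice.

Everything is a pure function of the seed, so fixtures need never be
stored on disk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw

from .cocoio import empty_coco, make_annotation, mask_bbox, save_json


@dataclass
class SceneRecord:
    """One image plus its instance annotations."""

    image: np.ndarray          # (H,W,3) uint8
    masks: list                # visible-part binary (H,W) masks
    boxes: np.ndarray          # (N,4) tight corner boxes x1,y1,x2,y2
    areas: np.ndarray          # (N,) 1-pixel counts
    instance_ids: list
    amodal_masks: list | None = None   # pre-occlusion blob masks (bookkeeping)
    seed: int = 0
    variant: str = "day"       # day | night
    view: str = "horizontal"   # horizontal | topdown

    def validate(self):
        h, w = self.image.shape[:2]
        for m, b, a in zip(self.masks, self.boxes, self.areas):
            assert m.shape == (h, w)
            assert int(m.sum()) == int(a)
            np.testing.assert_array_equal(mask_bbox(m), b)


@dataclass
class NightParams:
    brightness_scale: float = 0.35
    desaturation: float = 0.7      # 0 = keep color, 1 = grayscale
    noise_sd: float = 8.0


@dataclass
class SynthConfig:
    """Scene-generation parameters.

    The default frame is the wide 2:1 geometry of barn footage scaled for
    desk use (H=256, W=512); tiny fixtures use (64, 128).  Instance count
    and blob size ranges are inclusive.
    """

    image_size: tuple = (256, 512)            # (H, W)
    instance_range: tuple = (1, 4)
    blob_radius_range: tuple = (18, 40)       # semi-major axis, px
    overlap: bool = True                      # allow blob centers to cluster
    occluder_probability: float = 0.25        # fence bars
    night_probability: float = 0.0
    night: NightParams = field(default_factory=NightParams)
    view: str = "horizontal"
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if self.instance_range[0] < 1:
            raise ValueError("instance count must be >= 1")
        if self.blob_radius_range[0] <= 0:
            raise ValueError("blob sizes must be positive")
        if 2 * self.blob_radius_range[1] > min(h, w):
            raise ValueError(
                f"largest blob (diameter {2 * self.blob_radius_range[1]}) does not "
                f"fit the {h}x{w} image")


def _blob_mask(rng: np.random.Generator, shape, center, radius) -> np.ndarray:
    """Elongated body: union of a big ellipse, a head ellipse, boundary wobble."""
    h, w = shape
    cy, cx = center
    theta = rng.uniform(0, np.pi)
    a = radius
    b = radius * rng.uniform(0.42, 0.6)
    mask = np.zeros(shape, dtype=np.uint8)
    rr, cc = skdraw.ellipse(cy, cx, b, a, shape=shape, rotation=theta)
    mask[rr, cc] = 1
    # head at one end of the major axis
    hx = cx + 0.95 * a * np.cos(theta) * rng.choice([-1, 1])
    hy = cy - 0.95 * a * np.sin(theta)
    rr, cc = skdraw.ellipse(hy, hx, b * 0.62, b * 0.62, shape=shape)
    mask[rr, cc] = 1
    # low-frequency boundary noise: one or two extra overlapping lobes
    for _ in range(rng.integers(1, 3)):
        off = rng.uniform(-0.4, 0.4, size=2) * [b, a]
        rr, cc = skdraw.ellipse(cy + off[0], cx + off[1], b * rng.uniform(0.7, 1.0),
                                a * rng.uniform(0.6, 0.9), shape=shape,
                                rotation=theta + rng.uniform(-0.3, 0.3))
        mask[rr, cc] = 1
    return mask


def _background(rng: np.random.Generator, shape) -> np.ndarray:
    h, w = shape
    base = rng.uniform(70, 110)
    tex = ndimage.gaussian_filter(rng.normal(0, 1, size=(h, w)), sigma=6)
    tex = 25 * tex / (np.abs(tex).max() + 1e-9)
    grad = np.linspace(-12, 12, h)[:, None]
    gray = base + tex + grad
    img = np.stack([gray * 1.02, gray, gray * 0.92], axis=-1)
    return img


def night_transform(image: np.ndarray, params: NightParams,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Day image -> night variant: darken, desaturate, add sensor noise."""
    rng = rng if rng is not None else np.random.default_rng(0)
    img = np.asarray(image, dtype=float)
    gray = img.mean(axis=-1, keepdims=True)
    img = (1 - params.desaturation) * img + params.desaturation * gray
    img = img * params.brightness_scale
    if params.noise_sd > 0:
        img = img + rng.normal(0, params.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_scene(cfg: SynthConfig, rng: np.random.Generator | int | None = None
                   ) -> SceneRecord:
    """Draw one scene; fully determined by the generator state / seed."""
    seed = cfg.seed
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = int(rng) if rng is not None else cfg.seed
        rng = np.random.default_rng(seed)
    h, w = cfg.image_size
    img = _background(rng, (h, w))
    n = int(rng.integers(cfg.instance_range[0], cfg.instance_range[1] + 1))
    rmin, rmax = cfg.blob_radius_range
    # draw blob geometry
    full_masks, colors = [], []
    cluster = (rng.uniform(0.25, 0.75, size=2) * [h, w]) if cfg.overlap else None
    for i in range(n):
        radius = rng.uniform(rmin, rmax)
        if cluster is not None and rng.random() < 0.6:
            cy = np.clip(cluster[0] + rng.normal(0, 0.8 * radius), radius, h - radius)
            cx = np.clip(cluster[1] + rng.normal(0, 1.2 * radius), radius, w - radius)
        else:
            cy = rng.uniform(radius, h - radius)
            cx = rng.uniform(radius, w - radius)
        full_masks.append(_blob_mask(rng, (h, w), (cy, cx), radius))
        tone = rng.uniform(150, 210)
        colors.append(np.array([tone, tone * rng.uniform(0.72, 0.85),
                                tone * rng.uniform(0.68, 0.8)]))
    # composite back-to-front: later blobs occlude earlier ones
    visible = [m.copy() for m in full_masks]
    for i in range(n):
        for j in range(i + 1, n):
            visible[i][full_masks[j] > 0] = 0
    for i in range(n):
        body = full_masks[i] > 0
        speckle = ndimage.gaussian_filter(rng.normal(0, 1, size=(h, w)), sigma=2)
        shade = colors[i][None, None, :] + 18 * speckle[..., None]
        img[body] = shade[body]
    # fence-like occluders erase visibility but stay in the image
    if rng.random() < cfg.occluder_probability:
        bar_mask = np.zeros((h, w), dtype=bool)
        for _ in range(rng.integers(2, 5)):
            x0 = rng.integers(0, w - 4)
            bw = int(rng.integers(2, 6))
            bar_mask[:, x0:x0 + bw] = True
        img[bar_mask] = rng.uniform(35, 55)
        for m in visible:
            m[bar_mask] = 0
    variant = "day"
    if rng.random() < cfg.night_probability:
        img = night_transform(img, cfg.night, rng)
        variant = "night"
    else:
        img = np.clip(img, 0, 255).astype(np.uint8)
    keep = [i for i, m in enumerate(visible) if m.sum() > 0]
    masks = [visible[i] for i in keep]
    boxes = np.array([mask_bbox(m) for m in masks]).reshape(-1, 4)
    areas = np.array([int(m.sum()) for m in masks])
    return SceneRecord(image=img, masks=masks, boxes=boxes, areas=areas,
                       instance_ids=list(range(1, len(masks) + 1)),
                       amodal_masks=[full_masks[i] for i in keep],
                       seed=seed, variant=variant, view=cfg.view)


def scene_to_coco(record: SceneRecord, image_id: int, next_ann_id: int,
                  file_name: str) -> tuple[dict, list[dict]]:
    h, w = record.image.shape[:2]
    image_entry = {"id": int(image_id), "file_name": file_name,
                   "height": int(h), "width": int(w)}
    anns = [make_annotation(m, image_id, next_ann_id + i)
            for i, m in enumerate(record.masks)]
    return image_entry, anns


def generate_dataset(cfg: SynthConfig, n_scenes: int, split_fractions,
                     out_dir, seed: int | None = None, retry_cap: int = 10):
    """Write PNG images + per-split COCO JSON + a manifest TSV.

    Returns {split: annotation path}.  Scenes that come out with zero
    visible instances are redrawn (bounded retries).
    """
    fracs = list(split_fractions)
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    seed = cfg.seed if seed is None else seed
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    names = ["train", "val", "test"][:len(fracs)]
    counts = [int(np.floor(f * n_scenes)) for f in fracs]
    counts[-1] += n_scenes - sum(counts)
    split_of = sum(([nm] * c for nm, c in zip(names, counts)), [])
    cocos = {nm: empty_coco() for nm in names}
    manifest = []
    ann_id = 1
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_scenes * (retry_cap + 1)) % (2**31)
    si = 0
    for i in range(n_scenes):
        rec = None
        for _ in range(retry_cap + 1):
            rec = generate_scene(cfg, int(child_seeds[si]))
            si += 1
            if len(rec.masks) > 0:
                break
        if rec is None or len(rec.masks) == 0:
            raise RuntimeError("could not draw a scene with visible instances")
        split = split_of[i]
        fname = f"scene_{i:05d}.png"
        Image.fromarray(rec.image).save(out_dir / "images" / fname)
        img_entry, anns = scene_to_coco(rec, i + 1, ann_id, fname)
        ann_id += len(anns)
        cocos[split]["images"].append(img_entry)
        cocos[split]["annotations"].extend(anns)
        manifest.append((i + 1, split, rec.seed, rec.variant, rec.view))
    paths = {}
    for nm in names:
        p = out_dir / f"annotations_{nm}.json"
        save_json(cocos[nm], p)
        paths[nm] = p
    with open(out_dir / "manifest.tsv", "w", newline="") as fh:
        wtr = csv.writer(fh, delimiter="\t")
        wtr.writerow(["scene_id", "split", "seed", "variant", "view"])
        wtr.writerows(manifest)
    return paths


def tiny_scene_set(n: int = 8, seed: int = 0, image_size=(64, 128),
                   instance_range=(1, 3), blob_radius_range=(9, 16),
                   occluder_probability=0.25) -> list[SceneRecord]:
    """In-memory desk-scale fixture scenes (no files)."""
    cfg = SynthConfig(image_size=image_size, instance_range=instance_range,
                      blob_radius_range=blob_radius_range,
                      occluder_probability=occluder_probability, seed=seed)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n * 4) % (2**31)
    out, si = [], 0
    while len(out) < n and si < len(seeds):
        rec = generate_scene(cfg, int(seeds[si]))
        si += 1
        if len(rec.masks) > 0:
            out.append(rec)
    return out
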