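"""In-training stochastic augmentation.

Seven operations fire independently per sample, in a fixed order, each
with its own probability: shift/scale/rotate (p=0.5), brightness/contrast
(p=0.2), RGB shift (p=0.1), HSV shift (p=0.1), JPEG compression (p=0.2),
channel shuffle (p=0.1), median blur (p=0.1).  Geometric transforms are
applied jointly to image and masks (linear interpolation for the image,
nearest for masks), boxes are recomputed as tight boxes of the transformed
masks, and instances whose visible area vanishes are dropped.

The scale and rotation strengths are drawn as a limit l ~ U[0.1, 0.3] per
application, read as a scale fraction (scale ~ U[1-l, 1+l]) and radians
(angle ~ U[-l, +l], i.e. up to about +/-17 degrees).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor

from .cocoio import mask_bbox
from .synth import SceneRecord

log = logging.getLogger(__name__)


@dataclass
class AugmentationSpec:
    """Operation parameters and firing probabilities."""

    p_shift_scale_rotate: float = 0.5
    shift_fraction: float = 0.0625
    scale_rotate_limits: tuple = (0.1, 0.3)

    p_brightness_contrast: float = 0.2
    brightness_contrast_limits: tuple = (0.1, 0.3)

    p_rgb_shift: float = 0.1
    rgb_shift_max: float = 10.0

    p_hsv_shift: float = 0.1
    hsv_shift_max: tuple = (20.0, 30.0, 20.0)   # H,S,V in OpenCV-style units

    p_jpeg: float = 0.2
    jpeg_quality: tuple = (85, 95)

    p_channel_shuffle: float = 0.1

    p_median_blur: float = 0.1
    median_radius: int = 3

    def zeroed(self) -> "AugmentationSpec":
        """Copy with every probability forced to 0 (identity pipeline)."""
        return replace(self, p_shift_scale_rotate=0, p_brightness_contrast=0,
                       p_rgb_shift=0, p_hsv_shift=0, p_jpeg=0,
                       p_channel_shuffle=0, p_median_blur=0)


def _affine(record: SceneRecord, spec: AugmentationSpec,
            rng: np.random.Generator) -> SceneRecord:
    h, w = record.image.shape[:2]
    tx = rng.uniform(-spec.shift_fraction, spec.shift_fraction) * w
    ty = rng.uniform(-spec.shift_fraction, spec.shift_fraction) * h
    lo, hi = spec.scale_rotate_limits
    s = 1.0 + rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]) * rng.random()
    theta = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]) * rng.random()
    c, si = np.cos(theta), np.sin(theta)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    # forward map (row, col): q = s*R(p - center) + center + t ; invert for scipy
    fwd = s * np.array([[c, -si], [si, c]])
    inv = np.linalg.inv(fwd)
    offset = center - inv @ (center + np.array([ty, tx]))
    img = np.stack([
        ndimage.affine_transform(record.image[..., ch].astype(float), inv,
                                 offset=offset, order=1, mode="nearest")
        for ch in range(3)], axis=-1)
    img = np.clip(img, 0, 255).astype(np.uint8)
    masks, ids = [], []
    for m, iid in zip(record.masks, record.instance_ids):
        tm = ndimage.affine_transform(m.astype(np.uint8), inv, offset=offset,
                                      order=0, mode="constant", cval=0)
        if tm.sum() == 0:
            log.info("instance %s left the frame during affine augmentation", iid)
            continue
        masks.append(tm.astype(np.uint8))
        ids.append(iid)
    boxes = np.array([mask_bbox(m) for m in masks]).reshape(-1, 4)
    areas = np.array([int(m.sum()) for m in masks])
    return replace(record, image=img, masks=masks, boxes=boxes, areas=areas,
                   instance_ids=ids)


def _brightness_contrast(img, spec, rng):
    lo, hi = spec.brightness_contrast_limits
    beta = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
    alpha = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
    out = img.astype(float) * (1.0 + beta)
    mean = out.mean()
    out = (out - mean) * (1.0 + alpha) + mean
    return np.clip(out, 0, 255).astype(np.uint8)


def _rgb_shift(img, spec, rng):
    shift = rng.uniform(-spec.rgb_shift_max, spec.rgb_shift_max, size=3)
    return np.clip(img.astype(float) + shift, 0, 255).astype(np.uint8)


def _hsv_shift(img, spec, rng):
    dh, ds, dv = [rng.uniform(-m, m) for m in spec.hsv_shift_max]
    hsv = skcolor.rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] + dh * 2.0 / 360.0) % 1.0   # OpenCV hue unit = 2 deg
    hsv[..., 1] = np.clip(hsv[..., 1] + ds / 255.0, 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] + dv / 255.0, 0, 1)
    return (skcolor.hsv2rgb(hsv) * 255).round().clip(0, 255).astype(np.uint8)


def _jpeg(img, spec, rng):
    q = int(rng.integers(spec.jpeg_quality[0], spec.jpeg_quality[1] + 1))
    buf = io.BytesIO()
    Image.fromarray(img).save(buf, format="JPEG", quality=q)
    buf.seek(0)
    return np.asarray(Image.open(buf).convert("RGB"))


def _channel_shuffle(img, spec, rng):
    perm = rng.permutation(3)
    return img[..., perm]


def _median_blur(img, spec, rng):
    return np.stack([ndimage.median_filter(img[..., ch], size=spec.median_radius)
                     for ch in range(3)], axis=-1)


def augment_sample(record: SceneRecord, spec: AugmentationSpec,
                   rng: np.random.Generator | int) -> SceneRecord:
    """Apply the stochastic pipeline to one scene."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = record
    if rng.random() < spec.p_shift_scale_rotate:
        out = _affine(out, spec, rng)
    img = out.image
    if rng.random() < spec.p_brightness_contrast:
        img = _brightness_contrast(img, spec, rng)
    if rng.random() < spec.p_rgb_shift:
        img = _rgb_shift(img, spec, rng)
    if rng.random() < spec.p_hsv_shift:
        img = _hsv_shift(img, spec, rng)
    if rng.random() < spec.p_jpeg:
        img = _jpeg(img, spec, rng)
    if rng.random() < spec.p_channel_shuffle:
        img = _channel_shuffle(img, spec, rng)
    if rng.random() < spec.p_median_blur:
        img = _median_blur(img, spec, rng)
    if img is not out.image:
        out = replace(out, image=img)
    return out
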