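"""Prototype-based one-stage instance segmentation head.

The detector follows the YOLACT recipe: a ProtoNet generates k image-wide
prototype masks from the highest-resolution pyramid level, while shared
prediction heads emit, per anchor, class logits, SSD-style box offsets and
a k-vector of mask coefficients squashed into [-1,1] by tanh.  After
greedy NMS, each surviving detection's mask is the sigmoid of the
coefficient-weighted linear combination of prototypes, upsampled to image
size, optionally cropped to the predicted box, and binarized.

Coordinates are pixels, origin top-left; boxes are half-open
[x1,x2) x [y1,y2); mask area is the count of 1-pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .backbone import FPN, Backbone, BackboneConfig, Conv
from .nn import Tensor, concat

log = logging.getLogger(__name__)

# SSD box-encoding variances
VAR_CENTER = 0.1
VAR_SIZE = 0.2


@dataclass
class Detection:
    """One candidate instance."""

    box: np.ndarray          # (4,) x1,y1,x2,y2 image pixels, half-open
    score: float
    label: int = 1
    coeffs: np.ndarray | None = None   # (k,) in [-1,1]
    mask: np.ndarray | None = None     # (H,W) uint8, filled by assemble_masks
    anchor_index: int = -1


@dataclass
class AnchorSet:
    """Prior boxes tiling the pyramid levels (center-form cx,cy,w,h)."""

    boxes: np.ndarray                 # (A,4)
    level_sizes: list                 # [(Hl,Wl), ...]
    num_per_cell: int
    pos_iou: float = 0.5
    neg_iou: float = 0.4

    def __len__(self):
        return len(self.boxes)

    def corner_form(self) -> np.ndarray:
        b = self.boxes
        return np.stack([b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2,
                         b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2], axis=1)


@dataclass
class ModelConfig:
    """Detector hyperparameters (single foreground class by default)."""

    num_classes: int = 1                     # foreground classes; +1 background logit
    k: int = 32                              # prototype count
    aspect_ratios: tuple = (1.0, 0.5, 2.0)
    anchor_scales: tuple = (24, 48, 96, 192, 384)
    score_threshold: float = 0.05
    nms_iou: float = 0.5
    mask_threshold: float = 0.5
    crop_masks: bool = True
    crop_area_fraction: float = 0.25         # crop only instances smaller than this
    max_detections: int = 100
    head_channels: int | None = None         # defaults to fpn width


def build_anchors(image_size, level_sizes, scales, aspect_ratios,
                  pos_iou=0.5, neg_iou=0.4) -> AnchorSet:
    """Tile anchors over pyramid levels; centers always inside the image."""
    h, w = image_size
    boxes = []
    for (hl, wl), scale in zip(level_sizes, scales):
        sy, sx = h / hl, w / wl
        cy = (np.arange(hl) + 0.5) * sy
        cx = (np.arange(wl) + 0.5) * sx
        gy, gx = np.meshgrid(cy, cx, indexing="ij")
        for r in aspect_ratios:
            aw = scale * np.sqrt(r)
            ah = scale / np.sqrt(r)
            level = np.stack([gx.ravel(), gy.ravel(),
                              np.full(hl * wl, aw), np.full(hl * wl, ah)], axis=1)
            boxes.append(level)
        # interleave ratios per cell: reorder so cell-major, ratio-minor
    out = []
    offset = 0
    for (hl, wl) in level_sizes:
        n = hl * wl
        per_ratio = boxes[offset:offset + len(aspect_ratios)]
        stacked = np.stack(per_ratio, axis=1).reshape(-1, 4)  # cell-major
        out.append(stacked)
        offset += len(aspect_ratios)
    return AnchorSet(np.concatenate(out, axis=0), list(level_sizes),
                     len(aspect_ratios), pos_iou, neg_iou)


def encode_boxes(gt_corner: np.ndarray, anchors_center: np.ndarray) -> np.ndarray:
    """Corner-form ground truth -> SSD offsets relative to center-form anchors."""
    g = np.asarray(gt_corner, dtype=float)
    a = np.asarray(anchors_center, dtype=float)
    gcx = (g[:, 0] + g[:, 2]) / 2
    gcy = (g[:, 1] + g[:, 3]) / 2
    gw = g[:, 2] - g[:, 0]
    gh = g[:, 3] - g[:, 1]
    t = np.empty_like(g)
    t[:, 0] = (gcx - a[:, 0]) / a[:, 2] / VAR_CENTER
    t[:, 1] = (gcy - a[:, 1]) / a[:, 3] / VAR_CENTER
    t[:, 2] = np.log(gw / a[:, 2]) / VAR_SIZE
    t[:, 3] = np.log(gh / a[:, 3]) / VAR_SIZE
    return t


def decode_boxes(offsets: np.ndarray, anchors: AnchorSet, image_size) -> np.ndarray:
    """Offsets -> corner-form boxes clipped to the image."""
    t = np.asarray(offsets, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("box offsets contain non-finite values")
    a = anchors.boxes
    cx = t[:, 0] * VAR_CENTER * a[:, 2] + a[:, 0]
    cy = t[:, 1] * VAR_CENTER * a[:, 3] + a[:, 1]
    bw = np.exp(t[:, 2] * VAR_SIZE) * a[:, 2]
    bh = np.exp(t[:, 3] * VAR_SIZE) * a[:, 3]
    h, w = image_size
    boxes = np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=1)
    boxes[:, 0::2] = boxes[:, 0::2].clip(0, w)
    boxes[:, 1::2] = boxes[:, 1::2].clip(0, h)
    return boxes


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of corner-form boxes a (N,4) and b (M,4)."""
    a = np.atleast_2d(a).astype(float)
    b = np.atleast_2d(b).astype(float)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def nms(dets: list[Detection], iou_threshold: float, score_threshold: float) -> list[Detection]:
    """Greedy per-class suppression by descending score.

    Detections below the score threshold are dropped first; zero-area boxes
    are discarded with a warning.  Ties on score break toward the lower
    anchor (input) index, making the result deterministic.
    """
    kept_all = []
    valid = []
    for i, d in enumerate(dets):
        if d.score < score_threshold:
            continue
        x1, y1, x2, y2 = d.box
        if x2 <= x1 or y2 <= y1:
            log.warning("discarding degenerate box %s (score %.3f)", d.box, d.score)
            continue
        valid.append((i, d))
    for label in sorted({d.label for _, d in valid}):
        group = [(i, d) for i, d in valid if d.label == label]
        order = sorted(range(len(group)), key=lambda j: (-group[j][1].score, group[j][0]))
        boxes = np.array([group[j][1].box for j in order], dtype=float)
        suppressed = np.zeros(len(order), dtype=bool)
        for u in range(len(order)):
            if suppressed[u]:
                continue
            kept_all.append(group[order[u]][1])
            if u + 1 < len(order):
                ious = box_iou_matrix(boxes[u:u + 1], boxes[u + 1:])[0]
                suppressed[u + 1:] |= ious > iou_threshold
    kept_all.sort(key=lambda d: -d.score)
    return kept_all


def combine_prototypes(protos: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Coefficient-weighted prototype combination -> probability map.

    Returns sigmoid(sum_k coeffs[k] * protos[k]) at prototype resolution.
    """
    protos = np.asarray(protos, dtype=float)
    k, hp, wp = protos.shape
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (k,):
        raise ValueError(f"coefficient length {coeffs.shape} does not match "
                         f"prototype count {k}")
    logitmap = (coeffs @ protos.reshape(k, -1)).reshape(hp, wp)
    return 1.0 / (1.0 + np.exp(-logitmap))


def assemble_masks(protos: np.ndarray, dets: list[Detection], crop: bool,
                   mask_threshold: float, image_size=None,
                   crop_area_fraction: float = 0.25) -> list[Detection]:
    """Fill in binary masks from prototype combinations.

    For each detection the pre-sigmoid mask is protos . coeffs; after the
    sigmoid the map is bilinearly upsampled to image size, cropped to the
    (size-gated) predicted box, and binarized.  Detections whose final mask
    is empty are dropped.
    """
    protos = np.asarray(protos, dtype=float)
    k, hp, wp = protos.shape
    if image_size is None:
        image_size = (hp * 4, wp * 4)
    h, w = image_size
    kept = []
    flat = protos.reshape(k, -1)
    for d in dets:
        if d.coeffs is None or len(d.coeffs) != k:
            raise ValueError(f"coefficient length {None if d.coeffs is None else len(d.coeffs)} "
                             f"does not match prototype count {k}")
        prob = combine_prototypes(protos, d.coeffs)
        if (h, w) != (hp, wp):
            prob = ndimage.zoom(prob, (h / hp, w / wp), order=1, grid_mode=True,
                                mode="nearest")
        if crop:
            x1, y1, x2, y2 = d.box
            box_area = max(x2 - x1, 0) * max(y2 - y1, 0)
            if box_area < crop_area_fraction * h * w:
                m = np.zeros_like(prob)
                xi1, yi1 = int(np.floor(x1)), int(np.floor(y1))
                xi2, yi2 = int(np.ceil(x2)), int(np.ceil(y2))
                m[max(yi1, 0):max(yi2, 0), max(xi1, 0):max(xi2, 0)] = \
                    prob[max(yi1, 0):max(yi2, 0), max(xi1, 0):max(xi2, 0)]
                prob = m
        binary = (prob > mask_threshold).astype(np.uint8)
        if binary.sum() == 0:
            continue
        d.mask = binary
        kept.append(d)
    return kept


class ProtoNet:
    """Stack of 3x3 convs, one x2 upsample, and a final 1x1 to k prototypes."""

    def __init__(self, rng, in_channels, k, width=None):
        width = width or in_channels
        self.convs = [Conv(rng, in_channels, width, 3, 1),
                      Conv(rng, width, width, 3, 1)]
        self.post = Conv(rng, width, width, 3, 1)
        self.final = Conv(rng, width, k, 1, 1, 0)
        # positive bias keeps the ReLU-gated prototypes alive at the start of
        # training (an all-negative prototype layer receives no gradient)
        self.final.b.data[:] = 0.5

    def __call__(self, p3: Tensor) -> Tensor:
        x = p3
        for c in self.convs:
            x = c(x).relu()
        x = nn.upsample_nearest2(x)
        x = self.post(x).relu()
        return self.final(x).relu()       # nonnegative prototypes

    def parameters(self):
        ps = []
        for c in self.convs + [self.post, self.final]:
            ps += c.parameters()
        return ps


class PredictionHead:
    """Head shared across pyramid levels: class / box / coefficient branches."""

    def __init__(self, rng, in_channels, num_classes, k, num_anchors):
        self.tower = Conv(rng, in_channels, in_channels, 3, 1)
        self.cls = Conv(rng, in_channels, num_anchors * (num_classes + 1), 3, 1)
        self.box = Conv(rng, in_channels, num_anchors * 4, 3, 1)
        self.coef = Conv(rng, in_channels, num_anchors * k, 3, 1)
        self.num_classes, self.k, self.num_anchors = num_classes, k, num_anchors

    def __call__(self, p: Tensor):
        t = self.tower(p).relu()
        n, _, hl, wl = t.shape

        def flatten(x, d):
            # (N, A*d, H, W) -> (N, H*W*A, d), cell-major to match anchor order
            return x.reshape(n, self.num_anchors, d, hl, wl) \
                    .transpose(0, 3, 4, 1, 2).reshape(n, hl * wl * self.num_anchors, d)

        return (flatten(self.cls(t), self.num_classes + 1),
                flatten(self.box(t), 4),
                flatten(self.coef(t), self.k).tanh())

    def parameters(self):
        ps = []
        for c in [self.tower, self.cls, self.box, self.coef]:
            ps += c.parameters()
        return ps


class YolactModel:
    """Backbone -> FPN(+PSA) -> ProtoNet + shared heads."""

    def __init__(self, backbone_cfg: BackboneConfig, model_cfg: ModelConfig,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.backbone_cfg = backbone_cfg
        self.cfg = model_cfg
        self.backbone = Backbone(backbone_cfg, rng)
        self.fpn = FPN(self.backbone.stage_channels, backbone_cfg.fpn_channels,
                       backbone_cfg.attention, rng)
        width = backbone_cfg.fpn_channels
        self.protonet = ProtoNet(rng, width, model_cfg.k, model_cfg.head_channels)
        self.head = PredictionHead(rng, width, model_cfg.num_classes, model_cfg.k,
                                   len(model_cfg.aspect_ratios))
        self._anchor_cache: dict = {}

    def parameters(self):
        return (self.backbone.parameters() + self.fpn.parameters()
                + self.protonet.parameters() + self.head.parameters())

    def anchors_for(self, image_size, level_sizes) -> AnchorSet:
        key = (tuple(image_size), tuple(level_sizes))
        if key not in self._anchor_cache:
            self._anchor_cache[key] = build_anchors(
                image_size, level_sizes, self.cfg.anchor_scales,
                self.cfg.aspect_ratios)
        return self._anchor_cache[key]

    def forward(self, images) -> dict:
        """images: (N,3,H,W) normalized tensor/array."""
        x = Tensor.as_tensor(images)
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        h, w = x.shape[2], x.shape[3]
        stages = self.backbone(x)
        pyr = self.fpn(stages)
        protos = self.protonet(pyr.p_levels[0])
        outs = [self.head(p) for p in pyr.p_levels]
        cls = concat([o[0] for o in outs], axis=1)
        box = concat([o[1] for o in outs], axis=1)
        coef = concat([o[2] for o in outs], axis=1)
        level_sizes = [tuple(p.shape[2:]) for p in pyr.p_levels]
        anchors = self.anchors_for((h, w), level_sizes)
        if len(anchors) != cls.shape[1]:
            raise ValueError(f"anchor count {len(anchors)} does not match "
                             f"head output {cls.shape[1]}")
        return dict(cls=cls, box=box, coef=coef, protos=protos,
                    anchors=anchors, pyramid=pyr, image_size=(h, w))


def normalize_image(image: np.ndarray, mean, std) -> np.ndarray:
    """HWC uint8 image -> CHW float, per-channel standardized."""
    img = np.asarray(image, dtype=float)
    out = (img - np.asarray(mean)) / np.asarray(std)
    return out.transpose(2, 0, 1)


def model_inference(image: np.ndarray, model: YolactModel,
                    mean=(123.675, 116.28, 103.53),
                    std=(58.395, 57.12, 57.375)) -> list[Detection]:
    """Full pipeline on one HWC uint8 image -> final detections with masks."""
    x = normalize_image(image, mean, std)[None]
    out = model.forward(x)
    h, w = out["image_size"]
    cls = out["cls"].data[0]
    box = out["box"].data[0]
    coef = out["coef"].data[0]
    protos = out["protos"].data[0]
    anchors = out["anchors"]
    z = cls - cls.max(axis=1, keepdims=True)
    prob = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    dets = []
    boxes = decode_boxes(box, anchors, (h, w))
    for label in range(1, cls.shape[1]):
        scores = prob[:, label]
        idx = np.where(scores >= model.cfg.score_threshold)[0]
        for i in idx:
            dets.append(Detection(box=boxes[i], score=float(scores[i]), label=label,
                                  coeffs=coef[i], anchor_index=int(i)))
    dets = nms(dets, model.cfg.nms_iou, model.cfg.score_threshold)
    dets = dets[:model.cfg.max_detections]
    dets = assemble_masks(protos, dets, model.cfg.crop_masks,
                          model.cfg.mask_threshold, (h, w),
                          model.cfg.crop_area_fraction)
    return dets
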