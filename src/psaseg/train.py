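"""Loss functions, anchor target assignment, and the SGD training loop.

Anchors are positive when their best ground-truth IoU reaches 0.5 and
negative below 0.4 (the band between is ignored); every ground-truth box
additionally claims its single best anchor.  The classification branch is
softmax cross-entropy with online hard-negative mining at 3:1
negatives-to-positives; boxes use smooth-L1 on SSD-encoded offsets of the
positives; masks use per-pixel binary cross-entropy between the assembled
(cropped, pre-threshold) prototype combination and the matched ground-truth
mask at prototype resolution, normalized by the ground-truth box area.
Total = L_cls + 1.5 L_box + 6.125 L_mask.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import block_reduce

from . import nn
from .augment import AugmentationSpec, augment_sample
from .model import (AnchorSet, YolactModel, box_iou_matrix, encode_boxes,
                    normalize_image)
from .nn import SGD, Tensor, bce_with_logits, smooth_l1, softmax_cross_entropy
from .synth import SceneRecord


@dataclass
class TrainConfig:
    """Optimization recipe (full-scale defaults; desk runs override lr/epochs)."""

    batch_size: int = 8
    epochs: int = 50
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0005
    mean: tuple = (123.675, 116.28, 103.53)
    std: tuple = (58.395, 57.12, 57.375)
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    ohem_ratio: int = 3
    w_box: float = 1.5
    w_mask: float = 6.125
    clip_norm: float | None = 10.0
    warmup_steps: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.neg_iou >= self.pos_iou:
            raise ValueError("negative IoU threshold must be below the positive one")


def assign_targets(anchors: AnchorSet, gt_boxes: np.ndarray,
                   pos_iou: float | None = None, neg_iou: float | None = None):
    """Label every anchor positive / negative / ignore and match it to a gt.

    Returns (labels, matched_gt) where labels[a] is 1 / 0 / -1 and
    matched_gt[a] is the index of the best-overlapping ground truth
    (meaningful for positives).  With no ground truth all anchors are
    negative.  Each ground truth claims its best anchor (ties to the lower
    anchor index), so every instance gets at least one positive.
    """
    pos_iou = anchors.pos_iou if pos_iou is None else pos_iou
    neg_iou = anchors.neg_iou if neg_iou is None else neg_iou
    a = len(anchors)
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    if len(gt_boxes) == 0:
        return np.zeros(a, dtype=int), np.full(a, -1, dtype=int)
    iou = box_iou_matrix(anchors.corner_form(), gt_boxes)   # (A,G)
    best_gt = iou.argmax(axis=1)
    best_iou = iou.max(axis=1)
    labels = np.full(a, -1, dtype=int)
    labels[best_iou < neg_iou] = 0
    labels[best_iou >= pos_iou] = 1
    # force-match: each gt claims its best still-unclaimed anchor (ties and
    # conflicts resolve toward the lower anchor index / earlier gt)
    claimed = set()
    for g in range(len(gt_boxes)):
        for j in np.argsort(-iou[:, g], kind="stable"):
            if j not in claimed:
                labels[j] = 1
                best_gt[j] = g
                claimed.add(int(j))
                break
    return labels, best_gt


def mine_hard_negatives(logits: np.ndarray, neg_idx: np.ndarray,
                        n_keep: int) -> np.ndarray:
    """Indices of the n_keep negatives with the highest background CE loss."""
    neg_idx = np.asarray(neg_idx, dtype=np.intp)
    z = logits - logits.max(axis=1, keepdims=True)
    logp0 = z[:, 0] - np.log(np.exp(z).sum(axis=1))
    losses = -logp0[neg_idx]
    return neg_idx[np.argsort(-losses, kind="stable")[:n_keep]]


def _downsample_mask(mask: np.ndarray, proto_shape) -> np.ndarray:
    hp, wp = proto_shape
    h, w = mask.shape
    fy, fx = h // hp, w // wp
    if fy * hp == h and fx * wp == w and fy >= 1 and fx >= 1:
        red = block_reduce(mask.astype(float), (fy, fx), np.mean)
    else:
        ys = (np.arange(hp) * h / hp).astype(int)
        xs = (np.arange(wp) * w / wp).astype(int)
        red = mask[np.ix_(ys, xs)].astype(float)
    return (red >= 0.5).astype(float)


def compute_losses(out: dict, records: list[SceneRecord], cfg: TrainConfig,
                   max_mask_positives: int = 32):
    """Batch losses from a model forward pass.

    Returns a dict of scalar Tensors: cls, box, mask, total.
    """
    anchors: AnchorSet = out["anchors"]
    h, w = out["image_size"]
    n = out["cls"].shape[0]
    zero = Tensor(0.0)
    l_cls_t, l_box_t, l_mask_t = zero, zero, zero
    for i, rec in enumerate(records):
        cls_i = out["cls"][i]
        box_i = out["box"][i]
        coef_i = out["coef"][i]
        protos_i = out["protos"][i]
        labels, matched = assign_targets(anchors, rec.boxes, cfg.pos_iou, cfg.neg_iou)
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        npos = len(pos)
        # --- classification with hard-negative mining -----------------------
        n_keep = min(len(neg), cfg.ohem_ratio * max(npos, 1))
        hard_neg = mine_hard_negatives(cls_i.data, neg, n_keep)
        sel = np.concatenate([pos, hard_neg]).astype(np.intp)
        sel_labels = np.zeros(len(sel), dtype=int)
        sel_labels[:npos] = 1  # single foreground class
        ce = softmax_cross_entropy(cls_i.take_rows(sel), sel_labels)
        l_cls = ce.sum() * (1.0 / max(npos, 1))
        l_cls_t = l_cls_t + l_cls
        if npos == 0:
            continue
        # --- boxes ----------------------------------------------------------
        gt_for_pos = rec.boxes[matched[pos]]
        targets = encode_boxes(gt_for_pos, anchors.boxes[pos])
        l_box = smooth_l1(box_i.take_rows(pos), targets).sum() * (1.0 / npos)
        l_box_t = l_box_t + l_box
        # --- masks ----------------------------------------------------------
        k, hp, wp = protos_i.shape
        if npos > max_mask_positives:
            order = np.argsort(-np.asarray([rec.areas[matched[p]] for p in pos]))
            mpos = pos[order[:max_mask_positives]]
        else:
            mpos = pos
        gt_small = {}
        lm = zero
        flat_protos = protos_i.reshape(k, hp * wp)
        coefs = coef_i.take_rows(mpos)                       # (P,k)
        pre = coefs @ flat_protos                            # (P, hp*wp)
        sx, sy = wp / w, hp / h
        for row, p_idx in enumerate(mpos):
            g = int(matched[p_idx])
            if g not in gt_small:
                gt_small[g] = _downsample_mask(rec.masks[g], (hp, wp))
            gt = gt_small[g]
            x1, y1, x2, y2 = rec.boxes[g]
            cx1, cy1 = int(np.floor(x1 * sx)), int(np.floor(y1 * sy))
            cx2, cy2 = int(np.ceil(x2 * sx)), int(np.ceil(y2 * sy))
            crop = np.zeros((hp, wp))
            crop[cy1:cy2, cx1:cx2] = 1.0
            area = max(crop.sum(), 1.0)
            bce = bce_with_logits(pre[row].reshape(hp, wp), gt)
            lm = lm + (bce * Tensor(crop)).sum() * (1.0 / area)
        l_mask_t = l_mask_t + lm * (1.0 / len(mpos))
    inv_n = 1.0 / n
    l_cls_t = l_cls_t * inv_n
    l_box_t = l_box_t * inv_n
    l_mask_t = l_mask_t * inv_n
    total = l_cls_t + cfg.w_box * l_box_t + cfg.w_mask * l_mask_t
    return dict(cls=l_cls_t, box=l_box_t, mask=l_mask_t, total=total)


def _check_finite(losses: dict, epoch: int, batch_idx: int):
    for name, t in losses.items():
        v = float(t.data)
        if not np.isfinite(v):
            raise RuntimeError(
                f"non-finite {name} loss ({v}) in epoch {epoch}, batch {batch_idx}")


def train_loop(dataset: list[SceneRecord], model: YolactModel, cfg: TrainConfig,
               val_set: list[SceneRecord] | None = None,
               augmentation: AugmentationSpec | None = None,
               log_path=None, progress: bool = False):
    """SGD training with seeded shuffling; returns (model, per-epoch log).

    The model with the lowest validation total loss is restored at the end
    when a validation set is given.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    opt = SGD(params, cfg.lr, cfg.momentum, cfg.weight_decay, cfg.clip_norm)
    logrows = []
    best_val, best_state = np.inf, None
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        sums = dict(cls=0.0, box=0.0, mask=0.0, total=0.0)
        nb = 0
        for b0 in range(0, len(dataset), cfg.batch_size):
            batch_idx = order[b0:b0 + cfg.batch_size]
            recs = []
            for j in batch_idx:
                r = dataset[j]
                if augmentation is not None:
                    r = augment_sample(r, augmentation, rng)
                recs.append(r)
            imgs = np.stack([normalize_image(r.image, cfg.mean, cfg.std)
                             for r in recs])
            out = model.forward(imgs)
            losses = compute_losses(out, recs, cfg)
            _check_finite(losses, epoch, nb)
            opt.zero_grad()
            losses["total"].backward()
            if cfg.warmup_steps and step < cfg.warmup_steps:
                opt.lr = cfg.lr * (step + 1) / cfg.warmup_steps
            else:
                opt.lr = cfg.lr
            opt.step()
            step += 1
            for kk in sums:
                sums[kk] += float(losses[kk].data)
            nb += 1
        row = {"epoch": epoch, "lcls": sums["cls"] / nb, "lbox": sums["box"] / nb,
               "lmask": sums["mask"] / nb, "total": sums["total"] / nb}
        if val_set:
            imgs = np.stack([normalize_image(r.image, cfg.mean, cfg.std)
                             for r in val_set])
            vout = model.forward(imgs)
            vloss = float(compute_losses(vout, val_set, cfg)["total"].data)
            row["val_total"] = vloss
            if vloss < best_val:
                best_val = vloss
                best_state = [p.data.copy() for p in params]
        logrows.append(row)
        if progress:
            print(f"epoch {epoch:4d}  total {row['total']:.4f}")
    if best_state is not None:
        for p, d in zip(params, best_state):
            p.data = d
    if log_path is not None:
        write_loss_log(logrows, log_path)
    return model, logrows


def write_loss_log(logrows, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["epoch", "lcls", "lbox", "lmask", "total"]
    if logrows and "val_total" in logrows[0]:
        cols.append("val_total")
    with open(path, "w", newline="") as fh:
        wtr = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
        wtr.writeheader()
        wtr.writerows(logrows)
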