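"""COCO-style mask and box AP/AR evaluation, plus FPS measurement.

Average precision is the 101-point interpolated area under the
precision-recall curve, computed at IoU thresholds 0.50:0.05:0.95 and
summarized as AP50, AP75, mean AP, and the large-object variant (mask
area >= 96^2 px; size bounds 32^2 / 96^2 partition the instances).
Average recall is the mean over IoU thresholds of the recall at the
100-detections-per-image cap.  Matching is greedy in descending score,
each detection taking the highest-IoU not-yet-matched ground truth,
with out-of-size-range ground truths treated as ignore regions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .cocoio import ann_to_mask, rle_decode

IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)   # 0.50 ... 0.95
RECALL_GRID = np.linspace(0, 1, 101)
AREA_SMALL_MAX = 32 ** 2      # 1024 px
AREA_MEDIUM_MAX = 96 ** 2     # 9216 px
MAX_DETECTIONS = 100


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks of identical shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both masks are empty; IoU undefined")
    return float(np.logical_and(a, b).sum() / union)


def mask_iou_matrix(dets: list, gts: list) -> np.ndarray:
    """Pairwise IoU between two lists of binary masks (flattened once)."""
    if not dets or not gts:
        return np.zeros((len(dets), len(gts)))
    d = np.stack([np.asarray(m, dtype=bool).ravel() for m in dets]).astype(np.float64)
    g = np.stack([np.asarray(m, dtype=bool).ravel() for m in gts]).astype(np.float64)
    inter = d @ g.T
    union = d.sum(1)[:, None] + g.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def match_predictions(dets, gt, iou_threshold: float):
    """Greedy TP/FP flags for score-sorted detections against one scene.

    `dets` carry `.mask` (preferred) or `.box`; `gt` is a SceneRecord or a
    list of binary masks.  Returns (flags bool array, unmatched_gt count).
    """
    gt_masks = gt.masks if hasattr(gt, "masks") else list(gt)
    det_masks = [d.mask for d in dets]
    if any(m is None for m in det_masks):
        from .model import box_iou_matrix
        ious = box_iou_matrix(np.array([d.box for d in dets]).reshape(-1, 4),
                              np.asarray(gt.boxes))
    else:
        ious = mask_iou_matrix(det_masks, gt_masks)
    flags = np.zeros(len(dets), dtype=bool)
    taken = np.zeros(ious.shape[1], dtype=bool)
    for d in range(len(dets)):
        if ious.shape[1] == 0:
            break
        cand = np.where(~taken, ious[d], -1.0)
        g = int(cand.argmax())
        if cand[g] >= iou_threshold:
            flags[d] = True
            taken[g] = True
    return flags, int((~taken).sum())


def average_precision(flags, scores, n_gt: int) -> float:
    """101-point interpolated AP from TP flags, scores, and gt count."""
    if n_gt < 1:
        raise ValueError("average_precision requires at least one ground truth")
    flags = np.asarray(flags, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    tp = np.cumsum(flags[order])
    fp = np.cumsum(~flags[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    return _interp_ap(precision, recall)


def _interp_ap(precision, recall) -> float:
    if len(precision) == 0:
        return 0.0
    prec = precision.copy()
    for i in range(len(prec) - 2, -1, -1):       # envelope from the right
        prec[i] = max(prec[i], prec[i + 1])
    idx = np.searchsorted(recall, RECALL_GRID, side="left")
    vals = np.where(idx < len(prec), prec[np.minimum(idx, len(prec) - 1)], 0.0)
    return float(vals.mean())


@dataclass
class Metrics:
    ap50: float
    ap75: float
    ap_5095: float
    ap_5095_large: float
    ar_5095: float
    ar_5095_large: float
    pr_curves: dict = field(default_factory=dict, repr=False)

    def as_dict(self):
        return {k: getattr(self, k) for k in
                ("ap50", "ap75", "ap_5095", "ap_5095_large",
                 "ar_5095", "ar_5095_large")}


@dataclass
class EvalResult:
    mask: Metrics
    box: Metrics
    fps: float | None = None

    def as_dict(self):
        out = {"mask": self.mask.as_dict(), "box": self.box.as_dict()}
        if self.fps is not None:
            out["fps"] = self.fps
        return out

    def table(self) -> str:
        rows = ["metric            mask     box"]
        for k in ("ap50", "ap75", "ap_5095", "ap_5095_large",
                  "ar_5095", "ar_5095_large"):
            rows.append(f"{k:<16} {getattr(self.mask, k):7.4f} {getattr(self.box, k):7.4f}")
        if self.fps is not None:
            rows.append(f"{'fps':<16} {self.fps:7.2f}")
        return "\n".join(rows)


def _match_image(ious: np.ndarray, gt_ignore: np.ndarray, det_areas: np.ndarray,
                 area_rng, thr: float):
    """COCO-style per-image matching with ignore handling.

    Detections are assumed sorted by descending score; ground truths are
    ordered non-ignored first.  Returns (det_matched, det_ignored).
    """
    nd, ng = ious.shape
    gt_taken = np.full(ng, False)
    det_matched = np.zeros(nd, dtype=bool)
    det_ignored = np.zeros(nd, dtype=bool)
    for d in range(nd):
        best, best_g = thr - 1e-12, -1
        for g in range(ng):
            if gt_taken[g] and not gt_ignore[g]:
                continue
            if best_g > -1 and not gt_ignore[best_g] and gt_ignore[g]:
                break  # prefer real matches; ignored gts are sorted last
            if ious[d, g] < best:
                continue
            best, best_g = ious[d, g], g
        if best_g > -1:
            det_matched[d] = True
            gt_taken[best_g] = True
            det_ignored[d] = bool(gt_ignore[best_g])
        else:
            lo, hi = area_rng
            det_ignored[d] = not (lo <= det_areas[d] < hi)
    return det_matched, det_ignored


def _evaluate_type(per_image: list, area_rng) -> Metrics:
    """per_image: list of dicts with scores (sorted desc), ious (D,G), gt_areas."""
    ap = {}
    recalls = []
    curves = {}
    for thr in IOU_THRESHOLDS:
        all_scores, all_match, all_ignore = [], [], []
        npig = 0
        for im in per_image:
            gt_areas = im["gt_areas"]
            lo, hi = area_rng
            gt_ignore = ~((gt_areas >= lo) & (gt_areas < hi))
            order = np.argsort(gt_ignore, kind="mergesort")  # non-ignored first
            ious = im["ious"][:, order] if im["ious"].size else im["ious"]
            matched, ignored = _match_image(
                ious, gt_ignore[order], im["det_areas"], area_rng, thr)
            all_scores.append(im["scores"])
            all_match.append(matched)
            all_ignore.append(ignored)
            npig += int((~gt_ignore).sum())
        if npig == 0:
            ap[thr] = float("nan")
            recalls.append(float("nan"))
            continue
        scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
        matched = np.concatenate(all_match) if all_match else np.zeros(0, bool)
        ignored = np.concatenate(all_ignore) if all_ignore else np.zeros(0, bool)
        order = np.argsort(-scores, kind="mergesort")
        matched, ignored = matched[order], ignored[order]
        keep = ~ignored
        tp = np.cumsum(matched[keep])
        fp = np.cumsum(~matched[keep])
        recall = tp / npig
        precision = tp / np.maximum(tp + fp, 1)
        ap[thr] = _interp_ap(precision, recall)
        recalls.append(float(recall[-1]) if len(recall) else 0.0)
        curves[float(thr)] = (precision, recall)
    aps = np.array([ap[t] for t in IOU_THRESHOLDS])
    return dict(ap50=float(ap[0.5]), ap75=float(ap[0.75]),
                ap_5095=float(np.mean(aps)), ar_5095=float(np.mean(recalls)),
                curves=curves)


def evaluate(results_json, gt_json, fps: float | None = None) -> EvalResult:
    """COCO-style evaluation of a results file/dict against a gt file/dict."""
    from .cocoio import load_json
    gt = load_json(gt_json) if not isinstance(gt_json, dict) else gt_json
    res = load_json(results_json) if not isinstance(results_json, (list, dict)) else results_json
    if isinstance(res, dict):
        res = res.get("annotations", res)
    images = {im["id"]: im for im in gt["images"]}
    for r in res:
        if r["image_id"] not in images:
            raise ValueError(f"results reference unknown image id {r['image_id']}")
    gt_by_img = {i: [] for i in images}
    for a in gt["annotations"]:
        if a["image_id"] not in images:
            raise ValueError(f"annotation {a['id']} references unknown image id "
                             f"{a['image_id']}")
        gt_by_img[a["image_id"]].append(a)
    res_by_img = {i: [] for i in images}
    for r in res:
        res_by_img[r["image_id"]].append(r)

    per_image_mask, per_image_box = [], []
    for img_id, im in images.items():
        h, w = im["height"], im["width"]
        gts = gt_by_img[img_id]
        dts = sorted(res_by_img[img_id], key=lambda r: -r["score"])[:MAX_DETECTIONS]
        scores = np.array([d["score"] for d in dts], dtype=float)
        # masks
        gmasks = [ann_to_mask(a, h, w) for a in gts]
        dmasks = [rle_decode(d["segmentation"]) for d in dts if "segmentation" in d]
        if len(dmasks) == len(dts):
            mious = mask_iou_matrix(dmasks, gmasks)
            per_image_mask.append(dict(
                scores=scores, ious=mious,
                gt_areas=np.array([m.sum() for m in gmasks], dtype=float),
                det_areas=np.array([m.sum() for m in dmasks], dtype=float)))
        # boxes
        def xywh_to_corner(b):
            return [b[0], b[1], b[0] + b[2], b[1] + b[3]]
        from .model import box_iou_matrix
        gb = np.array([xywh_to_corner(a["bbox"]) for a in gts]).reshape(-1, 4)
        db = np.array([xywh_to_corner(d["bbox"]) for d in dts]).reshape(-1, 4)
        bious = box_iou_matrix(db, gb) if len(db) and len(gb) else np.zeros((len(db), len(gb)))
        per_image_box.append(dict(
            scores=scores, ious=bious,
            gt_areas=np.array([m.sum() for m in gmasks], dtype=float),
            det_areas=np.array([(b[2] - b[0]) * (b[3] - b[1]) for b in db],
                               dtype=float).reshape(-1)))

    def metrics(per_image):
        allr = _evaluate_type(per_image, (0.0, np.inf))
        large = _evaluate_type(per_image, (AREA_MEDIUM_MAX, np.inf))
        return Metrics(ap50=allr["ap50"], ap75=allr["ap75"], ap_5095=allr["ap_5095"],
                       ap_5095_large=large["ap_5095"], ar_5095=allr["ar_5095"],
                       ar_5095_large=large["ar_5095"], pr_curves=allr["curves"])

    return EvalResult(mask=metrics(per_image_mask), box=metrics(per_image_box),
                      fps=fps)


def measure_fps(model, image_set, warmup: int = 2) -> float:
    """Mean single-image inference rate after discarding warmup passes."""
    from .model import model_inference
    images = list(image_set)
    if warmup >= len(images):
        raise ValueError(f"warmup ({warmup}) must be smaller than the image "
                         f"set ({len(images)})")
    times = []
    for i, img in enumerate(images):
        t0 = time.perf_counter()
        model_inference(img, model)
        dt = time.perf_counter() - t0
        if i >= warmup:
            times.append(dt)
    return float(1.0 / np.mean(times))
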