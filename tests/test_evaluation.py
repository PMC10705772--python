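"""The COCO-style evaluator against an independently coded re-derivation."""

import numpy as np
import pytest

from psaseg.cocoio import empty_coco, make_annotation, rle_encode
from psaseg.evaluation import (IOU_THRESHOLDS, average_precision, evaluate,
                               mask_iou, match_predictions, measure_fps)
from psaseg.model import Detection


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def test_mask_iou_basic_cases():
    a = np.array([[1, 1], [0, 0]])
    b = np.array([[1, 0], [0, 0]])
    assert mask_iou(a, a) == 1.0
    assert mask_iou(a, 1 - a) == 0.0
    assert mask_iou(a, b) == 0.5
    with pytest.raises(ValueError, match="empty"):
        mask_iou(np.zeros((2, 2)), np.zeros((2, 2)))
    with pytest.raises(ValueError, match="shapes"):
        mask_iou(np.zeros((2, 2)), np.zeros((3, 2)))


def _disk(h, w, cy, cx, r):
    yy, xx = np.mgrid[:h, :w]
    return (((yy - cy) ** 2 + (xx - cx) ** 2) < r * r).astype(np.uint8)


def test_match_predictions_exact_and_duplicate():
    gt = [_disk(32, 32, 16, 16, 8)]
    d1 = Detection(box=np.zeros(4), score=0.9, mask=gt[0].copy())
    flags, unmatched = match_predictions([d1], gt, 0.5)
    assert flags.tolist() == [True] and unmatched == 0
    d2 = Detection(box=np.zeros(4), score=0.5, mask=gt[0].copy())
    flags, unmatched = match_predictions([d1, d2], gt, 0.5)
    assert flags.tolist() == [True, False] and unmatched == 0


def test_match_predictions_agrees_with_exhaustive_greedy_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        gts = [_disk(48, 48, *rng.integers(8, 40, 2), rng.integers(4, 10))
               for _ in range(3)]
        dets = []
        for s in sorted(rng.random(5), reverse=True):
            dets.append(Detection(box=np.zeros(4), score=float(s),
                                  mask=_disk(48, 48, *rng.integers(8, 40, 2),
                                             rng.integers(4, 10))))
        flags, unmatched = match_predictions(dets, gts, 0.5)
        taken = set()
        want = []
        for d in dets:
            ious = [(mask_iou(d.mask, g) if (d.mask.sum() or g.sum()) else 0.0, j)
                    for j, g in enumerate(gts) if j not in taken]
            ious = [(v, j) for v, j in ious if v >= 0.5]
            if ious:
                v, j = max(ious)
                taken.add(j)
                want.append(True)
            else:
                want.append(False)
        assert flags.tolist() == want
        assert unmatched == 3 - len(taken)


def test_average_precision_limit_cases():
    assert average_precision([True, True, True], [0.9, 0.8, 0.7], 3) == 1.0
    assert average_precision([False, False], [0.9, 0.8], 3) == 0.0
    with pytest.raises(ValueError):
        average_precision([True], [0.9], 0)


# ---------------------------------------------------------------------------
# Independent oracle evaluator: a from-scratch per-threshold re-derivation
# ---------------------------------------------------------------------------

def _oracle_eval(results, gt):
    """Straightforward dict-and-loop COCO mask evaluation (all + large)."""
    from psaseg.cocoio import ann_to_mask, rle_decode
    imgs = {im["id"]: im for im in gt["images"]}
    out = {}
    for area_lo in (0.0, 96.0 ** 2):
        aps, recalls = [], []
        for thr in IOU_THRESHOLDS:
            entries = []      # (score, tp, ignore)
            total_gt = 0
            for iid, im in imgs.items():
                h, w = im["height"], im["width"]
                gms = [ann_to_mask(a, h, w) for a in gt["annotations"]
                       if a["image_id"] == iid]
                ig = [not (area_lo <= m.sum()) for m in gms]
                total_gt += sum(1 for v in ig if not v)
                dts = sorted([r for r in results if r["image_id"] == iid],
                             key=lambda r: -r["score"])[:100]
                dms = [rle_decode(r["segmentation"]) for r in dts]
                used = [False] * len(gms)
                for r, dm in zip(dts, dms):
                    best, bj = -1.0, -1
                    for j, gm in enumerate(gms):
                        if used[j] and not ig[j]:
                            continue
                        if bj >= 0 and not ig[bj] and ig[j]:
                            break
                        u = np.logical_or(dm, gm).sum()
                        v = np.logical_and(dm, gm).sum() / u if u else 0.0
                        if v >= thr and v >= best:
                            best, bj = v, j
                    if bj >= 0:
                        used[bj] = True
                        entries.append((r["score"], True, ig[bj]))
                    else:
                        entries.append((r["score"], False,
                                        not (area_lo <= dm.sum())))
            if total_gt == 0:
                aps.append(np.nan)
                recalls.append(np.nan)
                continue
            entries.sort(key=lambda e: -e[0])
            tp = fp = 0
            pr = []
            for s, is_tp, ignore in entries:
                if ignore:
                    continue
                tp += is_tp
                fp += not is_tp
                pr.append((tp / (tp + fp), tp / total_gt))
            # 101-point interpolation
            ap = 0.0
            for r_thr in np.linspace(0, 1, 101):
                best_p = max((p for p, r in pr if r >= r_thr - 1e-12), default=0.0)
                ap += best_p / 101
            aps.append(ap)
            recalls.append(pr[-1][1] if pr else 0.0)
        key = "all" if area_lo == 0.0 else "large"
        out[key] = dict(ap50=aps[0], ap75=aps[5], ap=float(np.mean(aps)),
                        ar=float(np.mean(recalls)))
    return out


def _random_fixture(seed, n_images=3):
    """Synthetic gt + perturbed/noisy predictions in COCO dicts."""
    rng = np.random.default_rng(seed)
    gt = empty_coco()
    results = []
    ann_id = 1
    for iid in range(1, n_images + 1):
        h, w = 96, 128
        gt["images"].append({"id": iid, "file_name": f"{iid}.png",
                             "height": h, "width": w})
        n = rng.integers(1, 4)
        for _ in range(n):
            cy, cx = rng.integers(20, h - 20), rng.integers(20, w - 20)
            r = int(rng.integers(6, 18))
            m = _disk(h, w, cy, cx, r)
            gt["annotations"].append(make_annotation(m, iid, ann_id))
            ann_id += 1
            # perturbed copy as a detection, sometimes dropped
            if rng.random() < 0.85:
                dy, dx = rng.integers(-4, 5, 2)
                dm = _disk(h, w, cy + dy, cx + dx, max(3, r + rng.integers(-3, 4)))
                results.append({"image_id": iid, "category_id": 1,
                                "score": float(rng.random()),
                                "bbox": [1.0, 1.0, 5.0, 5.0],
                                "segmentation": rle_encode(dm)})
        # spurious false positives
        for _ in range(rng.integers(0, 3)):
            dm = _disk(h, w, rng.integers(10, h - 10), rng.integers(10, w - 10),
                       rng.integers(4, 12))
            results.append({"image_id": iid, "category_id": 1,
                            "score": float(rng.random()),
                            "bbox": [1.0, 1.0, 5.0, 5.0],
                            "segmentation": rle_encode(dm)})
    return results, gt


def test_evaluator_agrees_with_oracle_on_10_fixtures():
    for seed in range(10):
        results, gt = _random_fixture(seed)
        res = evaluate(results, gt)
        want = _oracle_eval(results, gt)
        assert res.mask.ap50 == pytest.approx(want["all"]["ap50"], abs=1e-6)
        assert res.mask.ap75 == pytest.approx(want["all"]["ap75"], abs=1e-6)
        assert res.mask.ap_5095 == pytest.approx(want["all"]["ap"], abs=1e-6)
        assert res.mask.ar_5095 == pytest.approx(want["all"]["ar"], abs=1e-6)
        if not np.isnan(want["large"]["ap"]):
            assert res.mask.ap_5095_large == pytest.approx(want["large"]["ap"], abs=1e-6)
            assert res.mask.ar_5095_large == pytest.approx(want["large"]["ar"], abs=1e-6)


def _verbatim_results(gt):
    results = []
    for a in gt["annotations"]:
        results.append({"image_id": a["image_id"], "category_id": 1,
                        "score": 0.9, "bbox": list(a["bbox"]),
                        "segmentation": dict(a["segmentation"])})
    return results


def test_perfect_predictions_score_exactly_one():
    gt = empty_coco()
    gt["images"].append({"id": 1, "file_name": "a.png", "height": 128, "width": 128})
    big = _disk(128, 128, 64, 64, 60)     # area >> 96^2: large category nonempty
    small = _disk(128, 128, 16, 16, 6)
    gt["annotations"].append(make_annotation(big, 1, 1))
    gt["annotations"].append(make_annotation(small, 1, 2))
    res = evaluate(_verbatim_results(gt), gt)
    for metrics in (res.mask, res.box):
        for v in metrics.as_dict().values():
            assert v == 1.0


def test_empty_predictions_score_exactly_zero():
    gt = empty_coco()
    gt["images"].append({"id": 1, "file_name": "a.png", "height": 128, "width": 128})
    gt["annotations"].append(make_annotation(_disk(128, 128, 64, 64, 60), 1, 1))
    res = evaluate([], gt)
    for metrics in (res.mask, res.box):
        for v in metrics.as_dict().values():
            assert v == 0.0


def test_ap_monotone_in_iou_threshold():
    for seed in (3, 11):
        results, gt = _random_fixture(seed)
        res = evaluate(results, gt)
        assert res.mask.ap50 >= res.mask.ap75 >= 0.0
        curves = res.mask.pr_curves
        # AP at successive thresholds never increases
        aps = [average_precision_from_curve(curves[t]) for t in sorted(curves)]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))


def average_precision_from_curve(curve):
    precision, recall = curve
    from psaseg.evaluation import _interp_ap
    return _interp_ap(precision.copy(), recall)


def test_false_positive_never_raises_ap_and_top_tp_never_lowers_it():
    results, gt = _random_fixture(2)
    base = evaluate(results, gt).mask.ap_5095
    fp = {"image_id": 1, "category_id": 1, "score": 0.99,
          "bbox": [0.0, 0.0, 4.0, 4.0],
          "segmentation": rle_encode(_disk(96, 128, 5, 5, 3))}
    with_fp = evaluate(results + [fp], gt).mask.ap_5095
    assert with_fp <= base + 1e-12
    a0 = gt["annotations"][0]
    tp = {"image_id": a0["image_id"], "category_id": 1, "score": 1.0,
          "bbox": list(a0["bbox"]), "segmentation": dict(a0["segmentation"])}
    with_tp = evaluate(results + [tp], gt).mask.ap_5095
    assert with_tp >= base - 1e-12


def test_unknown_image_id_rejected():
    gt = empty_coco()
    gt["images"].append({"id": 1, "file_name": "a.png", "height": 32, "width": 32})
    bad = [{"image_id": 99, "category_id": 1, "score": 0.5,
            "bbox": [0, 0, 5, 5], "segmentation": rle_encode(np.ones((32, 32)))}]
    with pytest.raises(ValueError, match="99"):
        evaluate(bad, gt)


def test_measure_fps_positive_and_warmup_guard(tiny_model_and_cfg, tiny_scenes):
    model, _ = tiny_model_and_cfg
    fps = measure_fps(model, [s.image for s in tiny_scenes[:4]], warmup=1)
    assert np.isfinite(fps) and fps > 0
    with pytest.raises(ValueError, match="warmup"):
        measure_fps(model, [tiny_scenes[0].image], warmup=1)
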