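"""COCO-format annotation and results I/O.

Binary masks travel as COCO run-length encodings: column-major (Fortran
order) runs, first run counting zeros.  Both the uncompressed ``counts``
list dialect and the compressed LEB128-style ASCII string dialect are
read; writing defaults to the uncompressed list, which is valid COCO and
plain JSON.  Polygon segmentations are rasterized on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from skimage import draw as skdraw


# ---------------------------------------------------------------------------
# RLE codec
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Binary (H,W) mask -> {'size': [H,W], 'counts': [...]} (lossless)."""
    mask = np.asarray(mask)
    h, w = mask.shape
    flat = mask.flatten(order="F").astype(np.uint8)
    edges = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], edges, [flat.size]])
    runs = np.diff(bounds).tolist()
    counts = ([0] + runs) if (flat.size and flat[0] == 1) else runs
    return {"size": [int(h), int(w)], "counts": [int(c) for c in counts]}


def rle_decode(rle: dict) -> np.ndarray:
    """RLE (counts list or compressed string) -> binary (H,W) uint8 mask."""
    h, w = rle["size"]
    counts = rle["counts"]
    if isinstance(counts, str):
        counts = _string_to_counts(counts)
    vals = (np.arange(len(counts)) % 2).astype(np.uint8)
    flat = np.repeat(vals, np.asarray(counts, dtype=np.int64))
    if flat.size != h * w:
        raise ValueError(f"RLE counts sum to {flat.size}, expected {h * w}")
    return flat.reshape((h, w), order="F")


def _counts_to_string(counts) -> str:
    """Delta + variable-length base-32 encoding (pycocotools-compatible)."""
    out = []
    for i, x in enumerate(counts):
        x = int(x)
        if i > 2:
            x -= int(counts[i - 2])
        more = True
        while more:
            c = x & 0x1F
            x >>= 5
            more = not ((x == 0 and not (c & 0x10)) or (x == -1 and (c & 0x10)))
            if more:
                c |= 0x20
            out.append(chr(c + 48))
    return "".join(out)


def _string_to_counts(s: str) -> list[int]:
    counts = []
    i = 0
    while i < len(s):
        x, k = 0, 0
        more = True
        while more:
            c = ord(s[i]) - 48
            x |= (c & 0x1F) << (5 * k)
            more = bool(c & 0x20)
            i += 1
            k += 1
        if c & 0x10 and not more:
            x |= -1 << (5 * k)  # sign extension
        if len(counts) > 2:
            x += counts[-2]
        counts.append(x)
    return counts


def rle_compress(rle: dict) -> dict:
    return {"size": rle["size"], "counts": _counts_to_string(rle["counts"])}


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def ann_to_mask(ann: dict, height: int, width: int) -> np.ndarray:
    """Segmentation of one annotation -> binary (H,W) mask."""
    seg = ann["segmentation"]
    if isinstance(seg, dict):
        return rle_decode(seg)
    mask = np.zeros((height, width), dtype=np.uint8)
    for poly in seg:
        xs = np.asarray(poly[0::2], dtype=float)
        ys = np.asarray(poly[1::2], dtype=float)
        rr, cc = skdraw.polygon(ys, xs, shape=(height, width))
        mask[rr, cc] = 1
    return mask


def mask_bbox(mask: np.ndarray) -> np.ndarray:
    """Tight half-open corner box (x1,y1,x2,y2) of a nonempty binary mask."""
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("mask is empty; no bounding box")
    return np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1], dtype=float)


def make_annotation(mask: np.ndarray, image_id: int, ann_id: int,
                    category_id: int = 1) -> dict:
    box = mask_bbox(mask)
    return {
        "id": int(ann_id),
        "image_id": int(image_id),
        "category_id": int(category_id),
        "segmentation": rle_encode(mask),
        "area": int(mask.sum()),
        "bbox": [float(box[0]), float(box[1]),
                 float(box[2] - box[0]), float(box[3] - box[1])],
        "iscrowd": 0,
    }


def detections_to_results(dets, image_id: int, category_id: int = 1) -> list[dict]:
    """Detections -> COCO results records (bbox xywh + RLE segmentation)."""
    out = []
    for d in dets:
        x1, y1, x2, y2 = [float(v) for v in d.box]
        rec = {
            "image_id": int(image_id),
            "category_id": int(category_id),
            "bbox": [x1, y1, x2 - x1, y2 - y1],
            "score": float(d.score),
        }
        if d.mask is not None:
            rec["segmentation"] = rle_encode(d.mask)
        out.append(rec)
    return out


def load_json(path):
    with open(path) as fh:
        return json.load(fh)


def save_json(obj, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh)


def empty_coco(categories=({"id": 1, "name": "pig"},)) -> dict:
    return {"images": [], "annotations": [], "categories": list(categories)}
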