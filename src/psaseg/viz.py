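"""Visualization: prototype decomposition, attention overlays, predictions.

All panels are min-max normalized individually; a flat map (max == min)
renders mid-gray rather than amplifying noise.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage

from .model import YolactModel, model_inference, normalize_image


def _norm_panel(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    lo, hi = m.min(), m.max()
    if hi - lo < 1e-12:
        return np.full_like(m, 0.5)
    return (m - lo) / (hi - lo)


def viz_prototypes(model: YolactModel, image: np.ndarray, out_path):
    """Per-prototype grid for the top detection: input | prototype |
    coefficient | coefficient-scaled product (signed colormap).

    Returns metadata (coefficients, prototype maps, products) or None when
    nothing is detected.
    """
    dets = model_inference(image, model)
    if not dets:
        print("no detections; nothing to visualize")
        return None
    det = dets[0]
    out = model.forward(normalize_image(image, (123.675, 116.28, 103.53),
                                        (58.395, 57.12, 57.375))[None])
    protos = out["protos"].data[0]
    k = protos.shape[0]
    products = protos * np.asarray(det.coeffs)[:, None, None]
    fig, axes = plt.subplots(k, 4, figsize=(10, 2.2 * k), squeeze=False)
    for i in range(k):
        axes[i][0].imshow(image)
        axes[i][1].imshow(_norm_panel(protos[i]), cmap="viridis")
        axes[i][2].bar([0], [det.coeffs[i]], color="tab:red" if det.coeffs[i] < 0
                       else "tab:blue")
        axes[i][2].set_ylim(-1, 1)
        vmax = max(np.abs(products).max(), 1e-9)
        axes[i][3].imshow(products[i], cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        for ax in axes[i]:
            ax.set_xticks([]), ax.set_yticks([])
    axes[0][0].set_title("input"), axes[0][1].set_title("prototype")
    axes[0][2].set_title("coefficient"), axes[0][3].set_title("product")
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=80)
    plt.close(fig)
    return dict(coeffs=np.asarray(det.coeffs), protos=protos, products=products)


def viz_attention(model: YolactModel, image: np.ndarray, out_dir):
    """Attention overlays for each FPN merge level.

    For every merge point: the channel gate projected onto the feature map
    (sum_c c6[c] * |m_c|), the spatial gate s7, and the fused PSA output
    magnitude, each upsampled to image size and alpha-blended on the input.
    Returns metadata holding the raw per-level gate arrays.
    """
    if model.fpn.attn is None:
        raise ValueError("model has attention slot 'none'; no attention to visualize")
    x = normalize_image(image, (123.675, 116.28, 103.53),
                        (58.395, 57.12, 57.375))[None]
    stages = model.backbone(x)
    pyr = model.fpn.forward(stages, collect_attention=True)
    h, w = image.shape[:2]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = []
    for lvl, (m, inter) in enumerate(zip(pyr.m_levels, pyr.attn_maps)):
        if inter is None:
            continue
        feat = np.abs(m.data[0])
        chan_map = (inter.c6[:, None, None] * feat).sum(axis=0)
        fused = feat.mean(axis=0)
        panels = {"channel": chan_map, "spatial": inter.s7, "fused": fused}
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, (name, panel) in zip(axes, panels.items()):
            up = ndimage.zoom(_norm_panel(panel),
                              (h / panel.shape[0], w / panel.shape[1]),
                              order=1, grid_mode=True, mode="nearest")
            ax.imshow(image)
            ax.imshow(up, cmap="inferno", alpha=0.55, vmin=0, vmax=1)
            ax.set_title(f"M{lvl + 3} {name}")
            ax.set_xticks([]), ax.set_yticks([])
        fig.savefig(out_dir / f"attention_m{lvl + 3}.png", dpi=80)
        plt.close(fig)
        meta.append(dict(level=lvl, c6=inter.c6, s7=inter.s7,
                         channel_map=chan_map, fused=fused))
    return meta


def draw_predictions(image: np.ndarray, dets, out_path):
    """Overlay predicted masks and boxes on the image."""
    fig, ax = plt.subplots(figsize=(8, 8 * image.shape[0] / image.shape[1]))
    ax.imshow(image)
    cmap = plt.get_cmap("tab10")
    for i, d in enumerate(dets):
        color = cmap(i % 10)
        if d.mask is not None:
            overlay = np.zeros(image.shape[:2] + (4,))
            overlay[d.mask > 0] = (*color[:3], 0.45)
            ax.imshow(overlay)
        x1, y1, x2, y2 = d.box
        ax.add_patch(plt.Rectangle((x1, y1), x2 - x1, y2 - y1, fill=False,
                                   edgecolor=color, linewidth=1.5))
        ax.text(x1, y1 - 2, f"{d.score:.2f}", color=color, fontsize=8)
    ax.set_xticks([]), ax.set_yticks([])
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=90, bbox_inches="tight")
    plt.close(fig)
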