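"""Residual backbones and a feature pyramid with pluggable merge-point attention.

The pyramid follows the usual top-down design: backbone stages C3-C5
(strides 8/16/32) are projected by 1x1 lateral convolutions, the top-down
pathway upsamples (nearest-neighbour, x2) and adds the lateral map, and a
3x3 convolution smooths each merged map M3-M5 into P3-P5; P6/P7 come from
stride-2 convolutions on P5/P6.  The attention slot fires on each merged
map (including the topmost lateral, which has no higher level to add)
*before* smoothing — i.e. exactly on the directly superimposed feature
maps.  P6/P7 receive no attention.

Three variants: ``resnet50``/``resnet101`` (bottleneck stacks) and a
``tiny`` three-stage basic-block network (widths 32/64/128) that keeps a
full forward pass on a 128x64 image well under a second on one CPU core.
No normalization layers are used; the desk-scale models this package
trains are small enough that fan-in-scaled initialization suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import PsaParams, psa_batched
from .nn import Parameter, Tensor, conv2d, he_init, max_pool2d, upsample_nearest2


class Conv:
    """Convolution layer: weight + bias pair."""

    def __init__(self, rng, cin, cout, k=3, stride=1, pad=None, bias=True):
        if pad is None:
            pad = k // 2
        self.stride, self.pad = stride, pad
        self.w = Parameter(he_init(rng, (cout, cin, k, k), fan_in=cin * k * k))
        self.b = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class BasicBlock:
    """Two 3x3 convs with a (projected) skip connection."""

    def __init__(self, rng, cin, cout, stride=1):
        self.conv1 = Conv(rng, cin, cout, 3, stride)
        self.conv2 = Conv(rng, cout, cout, 3, 1)
        self.proj = Conv(rng, cin, cout, 1, stride, 0) if (stride != 1 or cin != cout) else None

    def __call__(self, x):
        out = self.conv2(self.conv1(x).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (out + skip).relu()

    def parameters(self):
        ps = self.conv1.parameters() + self.conv2.parameters()
        if self.proj is not None:
            ps += self.proj.parameters()
        return ps


class Bottleneck:
    """1x1 -> 3x3 -> 1x1 bottleneck with expansion 4."""

    def __init__(self, rng, cin, mid, stride=1):
        cout = mid * 4
        self.conv1 = Conv(rng, cin, mid, 1, 1, 0)
        self.conv2 = Conv(rng, mid, mid, 3, stride)
        self.conv3 = Conv(rng, mid, cout, 1, 1, 0)
        self.proj = Conv(rng, cin, cout, 1, stride, 0) if (stride != 1 or cin != cout) else None

    def __call__(self, x):
        out = self.conv3(self.conv2(self.conv1(x).relu()).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (out + skip).relu()

    def parameters(self):
        ps = self.conv1.parameters() + self.conv2.parameters() + self.conv3.parameters()
        if self.proj is not None:
            ps += self.proj.parameters()
        return ps


@dataclass
class BackboneConfig:
    """Backbone + pyramid configuration."""

    variant: str = "tiny"              # tiny | resnet50 | resnet101
    fpn_channels: int = 256
    attention: str = "psa"             # psa | none (or a plug-in factory at FPN level)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("tiny", "resnet50", "resnet101"):
            raise ValueError(f"unknown backbone variant {self.variant!r}")
        if self.fpn_channels % 2 != 0:
            raise ValueError("fpn_channels must be even (PSA halves channels)")


class Backbone:
    """Residual feature extractor returning stride-8/16/32 stage outputs."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.variant = cfg.variant
        if cfg.variant == "tiny":
            self.stem = [Conv(rng, 3, 16, 3, 2), Conv(rng, 16, 32, 3, 2)]
            self.stages = [
                [BasicBlock(rng, 32, 32, stride=2)],
                [BasicBlock(rng, 32, 64, stride=2)],
                [BasicBlock(rng, 64, 128, stride=2)],
            ]
            self.stage_channels = [32, 64, 128]
        else:
            counts = [3, 4, 6, 3] if cfg.variant == "resnet50" else [3, 4, 23, 3]
            self.stem = [Conv(rng, 3, 64, 7, 2)]
            self.stages = []
            cin = 64
            for i, (mid, n) in enumerate(zip([64, 128, 256, 512], counts)):
                blocks = [Bottleneck(rng, cin, mid, stride=1 if i == 0 else 2)]
                cin = mid * 4
                for _ in range(n - 1):
                    blocks.append(Bottleneck(rng, cin, mid))
                self.stages.append(blocks)
            self.stage_channels = [512, 1024, 2048]  # C3, C4, C5

    def forward(self, images) -> list[Tensor]:
        x = Tensor.as_tensor(images)
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by 32 "
                f"(five stride-2 reductions down to P7)")
        for conv in self.stem:
            x = conv(x).relu()
        if self.variant != "tiny":
            x = max_pool2d(x, 2, 2)
        outs = []
        for stage in self.stages:
            for block in stage:
                x = block(x)
            outs.append(x)
        if self.variant != "tiny":
            outs = outs[1:]  # keep strides 8/16/32 (C3-C5)
        return outs

    __call__ = forward

    def parameters(self):
        ps = []
        for conv in self.stem:
            ps += conv.parameters()
        for stage in self.stages:
            for block in stage:
                ps += block.parameters()
        return ps


@dataclass
class PyramidFeatures:
    """Backbone stages, merged maps, and final pyramid levels."""

    c_levels: list  # stage outputs, strides 8/16/32
    m_levels: list  # merged maps (post-attention, pre-smoothing)
    p_levels: list  # P3..P7
    attn_maps: list | None = None  # per-merge AttentionIntermediates when collected


class PsaSlot:
    """Default attention plug-in: one PSA block."""

    def __init__(self, channels, rng):
        self.params = PsaParams.initialize(channels, rng)

    def apply(self, x: Tensor) -> Tensor:
        return psa_batched(x, self.params)

    def apply_detailed(self, x: Tensor):
        from .attention import _collect, csa_batched, ssa_batched
        e, ic = csa_batched(x, self.params)
        f, isp = ssa_batched(x, self.params)
        return e + f, _collect(ic, isp)

    def parameters(self):
        return self.params.parameters()


class FPN:
    """Feature pyramid with an attention slot at each top-down merge point."""

    def __init__(self, in_channels, out_channels=256, attention="psa",
                 rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.out_channels = out_channels
        self.laterals = [Conv(rng, c, out_channels, 1, 1, 0) for c in in_channels]
        self.smooths = [Conv(rng, out_channels, out_channels, 3, 1) for _ in in_channels]
        self.down6 = Conv(rng, out_channels, out_channels, 3, 2)
        self.down7 = Conv(rng, out_channels, out_channels, 3, 2)
        if attention == "psa":
            self.attn = [PsaSlot(out_channels, rng) for _ in in_channels]
        elif attention in (None, "none"):
            self.attn = None
        elif callable(attention):
            self.attn = [attention(out_channels, rng) for _ in in_channels]
        else:
            raise ValueError(f"unknown attention slot {attention!r}")

    def forward(self, stages: list[Tensor], collect_attention: bool = False
                ) -> PyramidFeatures:
        if len(stages) != len(self.laterals):
            raise ValueError(f"expected {len(self.laterals)} stage maps, got {len(stages)}")
        for i, s in enumerate(stages):
            want = self.laterals[i].w.shape[1]
            if s.shape[1] != want:
                raise ValueError(
                    f"stage {i} channel count {s.shape[1]} does not match "
                    f"lateral input width {want}")
        lats = [lat(s) for lat, s in zip(self.laterals, stages)]
        merged = [None] * len(lats)
        attn_maps = [None] * len(lats) if collect_attention else None
        top = len(lats) - 1
        for i in range(top, -1, -1):
            m = lats[i] if i == top else lats[i] + upsample_nearest2(merged[i + 1])
            if self.attn is not None:
                slot = self.attn[i]
                if collect_attention and hasattr(slot, "apply_detailed"):
                    m, attn_maps[i] = slot.apply_detailed(m)
                else:
                    m = slot.apply(m)
            merged[i] = m
        ps = [sm(m) for sm, m in zip(self.smooths, merged)]
        p6 = self.down6(ps[-1])
        p7 = self.down7(p6)
        return PyramidFeatures(c_levels=list(stages), m_levels=merged,
                               p_levels=ps + [p6, p7], attn_maps=attn_maps)

    __call__ = forward

    def parameters(self):
        ps = []
        for c in self.laterals + self.smooths + [self.down6, self.down7]:
            ps += c.parameters()
        if self.attn is not None:
            for a in self.attn:
                ps += a.parameters()
        return ps


def backbone_forward(image_batch, cfg: BackboneConfig | Backbone) -> list[Tensor]:
    """Run a backbone (built fresh from a config, or given) on an image batch."""
    model = cfg if isinstance(cfg, Backbone) else Backbone(cfg)
    return model(image_batch)


def fpn_forward(stages, cfg: BackboneConfig | FPN) -> PyramidFeatures:
    """Run an FPN on backbone stage maps.

    With a :class:`BackboneConfig`, a seeded pyramid is built whose lateral
    widths come from the stage maps themselves.
    """
    if isinstance(cfg, FPN):
        return cfg(stages)
    in_ch = [s.shape[1] for s in stages]
    fpn = FPN(in_ch, cfg.fpn_channels, cfg.attention, np.random.default_rng(cfg.seed))
    return fpn(stages)
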