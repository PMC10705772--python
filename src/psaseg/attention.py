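"""Pixel self-attention (PSA): parallel channel and spatial self-attention.

The block recalibrates a feature map X (C x H x W) twice, in parallel:

* Channel self-attention (CSA).  A 1x1 "value" projection halves the
  channels (C1 -> C3 after flattening); a 1x1 "query" projection collapses
  them to a single map whose H*W entries are softmax-normalized (C4 -> C5).
  Contracting C3 against C5 over spatial positions pools the value features
  under that spatial distribution; a 1x1 convolution restores C channels and
  a sigmoid yields the per-channel gate C6 in (0,1).  E = X * C6, broadcast
  over space.

* Spatial self-attention (SSA).  Two 1x1 projections halve the channels
  (S1 query, S2 value).  S1 is globally average-pooled to a C/2 vector S3,
  softmax over channels gives S6; contracting S6 against the flattened S2
  (S4) over channels gives one score per pixel, and a sigmoid produces the
  spatial gate S7 in (0,1).  F = X * S7, broadcast over channels.

The branch outputs are fused additively: Y = E + F.  The "element-wise
multiplication" of the C3*C5 and S6*S4 pairings is realized as tensor
contraction over the shared axis — the only reading consistent with the
declared output shapes (C6 a C-vector, S7 an H x W map).

All operations are differentiable through :mod:`psaseg.nn`, so PSA trains
end-to-end inside the feature pyramid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Parameter, Tensor, conv2d, he_init, softmax

REDUCTION = 2  # both branches project C -> C/2


@dataclass
class AttentionIntermediates:
    """The intermediate maps of one PSA application (single image)."""

    c1: np.ndarray  # C/2 x H x W        value projection
    c2: np.ndarray  # 1 x H x W          query projection
    c3: np.ndarray  # C/2 x (H*W)
    c4: np.ndarray  # (H*W,)
    c5: np.ndarray  # (H*W,)             softmax over positions
    c6: np.ndarray  # (C,)               channel gate in (0,1)
    s1: np.ndarray  # C/2 x H x W        query projection
    s2: np.ndarray  # C/2 x H x W        value projection
    s3: np.ndarray  # (C/2,)             global average pool of s1
    s4: np.ndarray  # C/2 x (H*W)
    s6: np.ndarray  # (C/2,)             softmax over channels
    s7: np.ndarray  # H x W              spatial gate in (0,1)


@dataclass
class PsaParams:
    """1x1-convolution weights of one PSA block (channels C, reduction 2)."""

    w_c_val: Parameter    # (C/2, C, 1, 1)
    b_c_val: Parameter
    w_c_query: Parameter  # (1, C, 1, 1)
    b_c_query: Parameter
    w_c_restore: Parameter  # (C, C/2, 1, 1)
    b_c_restore: Parameter
    w_s_query: Parameter  # (C/2, C, 1, 1)
    b_s_query: Parameter
    w_s_val: Parameter    # (C/2, C, 1, 1)
    b_s_val: Parameter
    channels: int = field(default=0)

    @classmethod
    def initialize(cls, channels: int, rng: np.random.Generator | int = 0) -> "PsaParams":
        if channels % REDUCTION != 0:
            raise ValueError(f"PSA requires an even channel count, got {channels}")
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        half = channels // REDUCTION

        def conv(co, ci):
            return Parameter(he_init(rng, (co, ci, 1, 1), fan_in=ci))

        def bias(co):
            return Parameter(np.zeros(co))

        return cls(
            w_c_val=conv(half, channels), b_c_val=bias(half),
            w_c_query=conv(1, channels), b_c_query=bias(1),
            w_c_restore=conv(channels, half), b_c_restore=bias(channels),
            w_s_query=conv(half, channels), b_s_query=bias(half),
            w_s_val=conv(half, channels), b_s_val=bias(half),
            channels=channels,
        )

    def parameters(self) -> list[Parameter]:
        return [self.w_c_val, self.b_c_val, self.w_c_query, self.b_c_query,
                self.w_c_restore, self.b_c_restore,
                self.w_s_query, self.b_s_query, self.w_s_val, self.b_s_val]


def _validate(x: np.ndarray):
    if x.ndim != 3:
        raise ValueError(f"expected a C x H x W feature map, got shape {x.shape}")
    c = x.shape[0]
    if c % REDUCTION != 0:
        raise ValueError(f"PSA needs an even channel count (both branches halve "
                         f"channels); got C={c}")
    if not np.isfinite(x).all():
        raise ValueError("feature map contains non-finite entries")


def _as_batched(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        t = x
    else:
        arr = np.asarray(x, dtype=float)
        _validate(arr)
        t = Tensor(arr)
    if t.ndim == 3:
        return t.reshape((1,) + t.shape), True
    return t, False


def csa_batched(x: Tensor, p: PsaParams):
    """Channel branch on a batched (N,C,H,W) tensor; returns (e, inter dict)."""
    n, c, h, w = x.shape
    c1 = conv2d(x, p.w_c_val, p.b_c_val)                     # N,C/2,H,W
    c2 = conv2d(x, p.w_c_query, p.b_c_query)                 # N,1,H,W
    c3 = c1.reshape(n, c // 2, h * w)
    c4 = c2.reshape(n, h * w)
    c5 = softmax(c4, axis=1)                                 # over positions
    pooled = c3 @ c5.reshape(n, h * w, 1)                    # N,C/2,1
    z = conv2d(pooled.reshape(n, c // 2, 1, 1), p.w_c_restore, p.b_c_restore)
    c6 = z.sigmoid().reshape(n, c, 1, 1)                     # channel gate
    e = x * c6
    inter = dict(c1=c1, c2=c2, c3=c3, c4=c4, c5=c5, c6=c6.reshape(n, c))
    return e, inter


def ssa_batched(x: Tensor, p: PsaParams):
    """Spatial branch on a batched (N,C,H,W) tensor; returns (f, inter dict)."""
    n, c, h, w = x.shape
    s1 = conv2d(x, p.w_s_query, p.b_s_query)                 # N,C/2,H,W
    s2 = conv2d(x, p.w_s_val, p.b_s_val)                     # N,C/2,H,W
    s3 = s1.mean(axis=(2, 3))                                # global average pool
    s6 = softmax(s3, axis=1)                                 # over channels
    s4 = s2.reshape(n, c // 2, h * w)
    scores = s6.reshape(n, 1, c // 2) @ s4                   # N,1,HW
    s7 = scores.reshape(n, 1, h, w).sigmoid()                # spatial gate
    f = x * s7
    inter = dict(s1=s1, s2=s2, s3=s3, s4=s4, s6=s6, s7=s7.reshape(n, h, w))
    return f, inter


def psa_batched(x: Tensor, p: PsaParams) -> Tensor:
    e, _ = csa_batched(x, p)
    f, _ = ssa_batched(x, p)
    return e + f


def _collect(inter_c: dict | None, inter_s: dict | None) -> AttentionIntermediates:
    def g(d, k):
        return np.asarray(d[k].data[0]) if d is not None else None

    return AttentionIntermediates(
        c1=g(inter_c, "c1"), c2=g(inter_c, "c2"), c3=g(inter_c, "c3"),
        c4=g(inter_c, "c4"), c5=g(inter_c, "c5"), c6=g(inter_c, "c6"),
        s1=g(inter_s, "s1"), s2=g(inter_s, "s2"), s3=g(inter_s, "s3"),
        s4=g(inter_s, "s4"), s6=g(inter_s, "s6"), s7=g(inter_s, "s7"),
    )


def channel_self_attention(x, params: PsaParams):
    """CSA on a single C x H x W map; returns (E, intermediates)."""
    xb, _ = _as_batched(x)
    e, inter = csa_batched(xb, params)
    return np.asarray(e.data[0]), _collect(inter, None)


def spatial_self_attention(x, params: PsaParams):
    """SSA on a single C x H x W map; returns (F, intermediates)."""
    xb, _ = _as_batched(x)
    f, inter = ssa_batched(xb, params)
    return np.asarray(f.data[0]), _collect(None, inter)


def pixel_self_attention(x, params: PsaParams):
    """Full PSA on a single C x H x W map: Y = E + F."""
    xb, _ = _as_batched(x)
    e, ic = csa_batched(xb, params)
    f, isp = ssa_batched(xb, params)
    y = e + f
    return np.asarray(y.data[0]), _collect(ic, isp)
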