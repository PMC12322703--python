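"""Progressive feature fusion module (PFFM) built from weighted
self-attention fusion (WSAF) units.

WSAF fuses two feature maps F01, F02 of possibly different scales:

1. the operand that does not define the output geometry is bilinearly
   resampled and projected by a 1x1 convolution to the other's channels;
2. F1 = W1 * F01 + W2 * F02 with learnable unconstrained scalars W1, W2
   (both initialised to 1);
3. a per-channel gate g = sigmoid(GAP(F1)) filters fusion redundancy:
   z = g * F1 + F1;
4. multi-head self-attention refines z residually: queries are all spatial
   tokens, keys/values are tokens average-pooled to at most ``kv_limit``;
   a depthwise 5x5 convolution on z (local positional enhancement) is added
   alongside the attention output, so the unit keeps locality while the
   attention contributes long-range context:
   out = z + Attn(z) + DWConv(z).

All projections are bias-free, so an all-zero pyramid maps to an all-zero
output.

The progressive recipe fuses the backbone pyramid (a, b, c) = (stride 32,
16, 8) into the three head inputs with five distinct units, the inner
ab/bc units being shared between the outer expressions:

    ab = WSAF(a, b)      bc = WSAF(b, c)
    A  = WSAF(a, bc)     B = WSAF(ab, bc)     C = WSAF(c, ab)

A/B/C leave at strides 32/16/8.  For B the first operand (ab, stride 32) is
the one aligned: the output follows the operand whose stride matches the
middle head slot.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from . import nn
from .flops import attn_spec, conv_spec
from .nn import Tensor, resize_bilinear, softmax
from .nn.tensor import adaptive_avg_pool2d

KV_LIMIT = 441  # pooled key/value token budget (21 x 21)


def kv_grid(h: int, w: int, limit: int = KV_LIMIT) -> tuple[int, int]:
    """Key/value token grid: identity when within budget, else the square
    grid of side floor(sqrt(limit))."""
    if h * w <= limit:
        return h, w
    side = int(math.isqrt(limit))
    return min(h, side), min(w, side)


@dataclass
class FusedTriple:
    """Head inputs at strides 32 (A), 16 (B), 8 (C)."""

    A: Tensor
    B: Tensor
    C: Tensor


class WSAF(nn.Module):
    """Weighted self-attention fusion of two feature maps.

    ``align_first`` selects which operand is resampled/projected: by default
    the second operand is aligned to the first's geometry; with
    ``align_first=True`` the roles swap and the output follows the second.
    """

    def __init__(self, channels: int, align_channels: int, heads: int = 4,
                 kv_limit: int = KV_LIMIT, align_first: bool = False):
        super().__init__()
        if channels % heads:
            raise ValueError("channels must be divisible by heads")
        self.channels, self.heads, self.kv_limit = channels, heads, kv_limit
        self.align_first = align_first
        self.align_proj = nn.Conv2d(align_channels, channels, 1)
        self.w1 = nn.Parameter([1.0])
        self.w2 = nn.Parameter([1.0])
        self.to_q = nn.Conv2d(channels, channels, 1)
        self.to_k = nn.Conv2d(channels, channels, 1)
        self.to_v = nn.Conv2d(channels, channels, 1)
        self.pos = nn.Conv2d(channels, channels, 5, padding=2, groups=channels)

    def _attend(self, z: Tensor) -> Tensor:
        n, c, h, w = z.shape
        nh, dh = self.heads, c // self.heads
        q = self.to_q(z).reshape(n, nh, dh, h * w).transpose(0, 1, 3, 2)
        kh, kw = kv_grid(h, w, self.kv_limit)
        zp = adaptive_avg_pool2d(z, kh, kw) if (kh, kw) != (h, w) else z
        nkv = kh * kw
        k = self.to_k(zp).reshape(n, nh, dh, nkv)
        v = self.to_v(zp).reshape(n, nh, dh, nkv).transpose(0, 1, 3, 2)
        scores = (q * (1.0 / math.sqrt(dh))) @ k                     # (N,h,HW,nkv)
        out = softmax(scores, axis=-1) @ v                           # (N,h,HW,dh)
        return out.transpose(0, 1, 3, 2).reshape(n, c, h, w)

    def forward(self, f01: Tensor, f02: Tensor) -> Tensor:
        if self.align_first:
            target = f02
            aligned = self.align_proj(resize_bilinear(f01, f02.shape[2], f02.shape[3]))
            f1 = self.w1.reshape(1, 1, 1, 1) * aligned + self.w2.reshape(1, 1, 1, 1) * target
        else:
            aligned = self.align_proj(resize_bilinear(f02, f01.shape[2], f01.shape[3]))
            f1 = self.w1.reshape(1, 1, 1, 1) * f01 + self.w2.reshape(1, 1, 1, 1) * aligned
        gate = f1.mean(axis=(2, 3), keepdims=True).sigmoid()
        z = gate * f1 + f1
        return z + self._attend(z) + self.pos(z)

    def flop_specs(self, out_shape, align_in_channels=None):
        c, h, w = out_shape
        ca = align_in_channels if align_in_channels is not None else self.align_proj.cin
        kh, kw = kv_grid(h, w, self.kv_limit)
        specs = [
            conv_spec("wsaf.align_proj", 1, ca, c, h, w),
            conv_spec("wsaf.q", 1, c, c, h, w),
            conv_spec("wsaf.k", 1, c, c, kh, kw),
            conv_spec("wsaf.v", 1, c, c, kh, kw),
            attn_spec("wsaf.attn", h * w, kh * kw, c),
            conv_spec("wsaf.pos", 5, c, c, h, w, groups=c),
        ]
        return specs, out_shape


class PFFM(nn.Module):
    """Five-unit progressive fusion of the backbone pyramid."""

    def __init__(self, channels: tuple[int, int, int] = (512, 256, 128),
                 heads: int = 4, kv_limit: int = KV_LIMIT):
        super().__init__()
        ca, cb, cc = channels
        self.channels = channels
        self.unit_bc = WSAF(cb, cc, heads, kv_limit)
        self.unit_ab = WSAF(ca, cb, heads, kv_limit)
        self.unit_A = WSAF(ca, cb, heads, kv_limit)               # aligns bc (cb ch)
        self.unit_B = WSAF(cb, ca, heads, kv_limit, align_first=True)  # aligns ab
        self.unit_C = WSAF(cc, ca, heads, kv_limit)               # aligns ab

    def forward(self, a: Tensor, b: Tensor, c: Tensor) -> FusedTriple:
        bc = self.unit_bc(b, c)
        ab = self.unit_ab(a, b)
        A = self.unit_A(a, bc)
        B = self.unit_B(ab, bc)
        C = self.unit_C(c, ab)
        return FusedTriple(A=A, B=B, C=C)

    def flop_specs(self, pyramid_shapes):
        (sa, sb, sc) = pyramid_shapes       # (C,H,W) for a, b, c
        specs = []
        for name, unit, out_shape in [
            ("pffm.bc", self.unit_bc, sb),
            ("pffm.ab", self.unit_ab, sa),
            ("pffm.A", self.unit_A, sa),
            ("pffm.B", self.unit_B, sb),
            ("pffm.C", self.unit_C, sc),
        ]:
            sub, _ = unit.flop_specs(out_shape)
            specs.extend(LayerFlopSpecRenamed(s, name) for s in sub)
        return specs, pyramid_shapes


def LayerFlopSpecRenamed(s, prefix):
    from dataclasses import replace
    return replace(s, name=f"{prefix}.{s.name}")
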