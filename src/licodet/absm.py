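"""Adaptive background suppression module (ABSM).

Two-stage gating against cluttered vegetated backgrounds:

1. *Channel refinement.*  The feature map is compressed by a depthwise 7x7
   stride-2 convolution; each of the C channels then becomes one attention
   token whose embedding is its flattened compressed response.  Depthwise
   convolutions produce queries/keys/values, multi-head scaled dot-product
   attention mixes the CxC channel-similarity structure, and a softmax over
   globally pooled channel responses yields channel weights summing to 1.
   The input is rescaled per channel by C * weight, so uniform weights leave
   it untouched (identity on average).
2. *Coordinate-aware spatial gating.*  Per-pixel channel mean and max of the
   refined map form a 2-channel spatial statistic; pooling it along width
   and height gives directional profiles which a shared 1-D convolution
   turns into a coordinate gate sigmoid(p_h + p_w).  A 1x1 convolution over
   the gated statistic yields a second sigmoid gate.  The output is the
   refined map scaled by both gates, so the multiplicative factor lies in
   (0, 1) and, with all weights zero, equals exactly 1/4.

All projections are bias-free.
"""
from __future__ import annotations

import math

from . import nn
from .flops import attn_spec, conv1d_spec, conv_spec
from .nn import Tensor, concat, softmax


class ABSM(nn.Module):
    def __init__(self, channels: int, heads: int = 4, compress_stride: int = 2,
                 qkv_kernel: int = 7, profile_kernel: int = 3):
        super().__init__()
        if channels % heads:
            raise ValueError(f"channels ({channels}) must be divisible by heads ({heads})")
        if compress_stride < 1:
            raise ValueError("compress_stride must be >= 1")
        self.channels, self.heads = channels, heads
        self.compress_stride = compress_stride
        self.qkv_kernel = qkv_kernel
        self.profile_kernel = profile_kernel
        c = channels
        self.compress = nn.Conv2d(c, c, 7, stride=compress_stride, padding=3, groups=c)
        self.to_q = nn.Conv2d(c, c, qkv_kernel, padding=qkv_kernel // 2, groups=c)
        self.to_k = nn.Conv2d(c, c, qkv_kernel, padding=qkv_kernel // 2, groups=c)
        self.to_v = nn.Conv2d(c, c, qkv_kernel, padding=qkv_kernel // 2, groups=c)
        self.profile_conv = nn.Conv1d(2, 1, profile_kernel, padding=profile_kernel // 2)
        self.spatial_conv = nn.Conv2d(2, 1, 1)

    # -- channel stage -----------------------------------------------------
    def channel_weights(self, x: Tensor) -> Tensor:
        """Softmax channel weights, shape (N, C); rows sum to 1."""
        n, c, _, _ = x.shape
        z = self.compress(x)
        d = z.shape[2] * z.shape[3]
        h = self.heads if d % self.heads == 0 else 1  # token dim must split across heads
        dh = d // h
        q = self.to_q(z).reshape(n, c, h, dh).transpose(0, 2, 1, 3)
        k = self.to_k(z).reshape(n, c, h, dh).transpose(0, 2, 1, 3)
        v = self.to_v(z).reshape(n, c, h, dh).transpose(0, 2, 1, 3)
        scores = (q * (1.0 / math.sqrt(dh))) @ k.transpose(0, 1, 3, 2)   # (N,h,C,C)
        mixed = softmax(scores, axis=-1) @ v                              # (N,h,C,dh)
        mixed = mixed.transpose(0, 2, 1, 3).reshape(n, c, d)
        pooled = mixed.mean(axis=2)                                       # (N,C)
        return softmax(pooled, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        n, c, hh, ww = x.shape
        w = self.channel_weights(x)
        f1 = x * (w * float(c)).reshape(n, c, 1, 1)
        stats = concat([f1.mean(axis=1, keepdims=True), f1.max(axis=1, keepdims=True)], axis=1)
        prof_h = self.profile_conv(stats.mean(axis=3))                    # (N,1,H)
        prof_w = self.profile_conv(stats.mean(axis=2))                    # (N,1,W)
        coord = (prof_h.reshape(n, 1, hh, 1) + prof_w.reshape(n, 1, 1, ww)).sigmoid()
        gated_stats = stats * coord
        spatial = self.spatial_conv(gated_stats).sigmoid()                # (N,1,H,W)
        return f1 * coord * spatial

    # -- accounting --------------------------------------------------------
    def flop_specs(self, in_shape):
        c, h, w = in_shape
        s = self.compress_stride
        hp, wp = -(-h // s), -(-w // s)
        d = hp * wp
        specs = [conv_spec("absm.compress", 7, c, c, hp, wp, groups=c)]
        for nm in ("q", "k", "v"):
            specs.append(conv_spec(f"absm.{nm}", self.qkv_kernel, c, c, hp, wp, groups=c))
        specs.append(attn_spec("absm.attn", c, c, d))
        kp = self.profile_kernel
        specs.append(conv1d_spec("absm.profile_h", kp, 2, 1, h))
        specs.append(conv1d_spec("absm.profile_w", kp, 2, 1, w))
        specs.append(conv_spec("absm.spatial", 1, 2, 1, h, w))
        return specs, in_shape
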