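"""Lightweight multi-scale module (LMSM).

Wild licorice spans a huge size range within one frame, so a cheap block
extracts features at several receptive fields at once:

* *Channel-information branch* — local p x p average pooling, then global
  average pooling, a 1-D convolution along the channel axis, and broadcast
  restoration ("anti-pooling") back to the map size.  It acts as a sigmoid
  gate on the multi-scale branch.
* *Multi-scale branch* — a 1x1 convolution reduces C to a small inner width,
  the result splits into four equal channel groups, each passes a 3x3
  convolution at a different dilation (receptive field 2d+1 per axis), the
  groups concatenate and a 1x1 convolution restores C channels.

Fusion is ``branch2 * sigmoid(branch1) + x``: with the multi-scale branch at
zero weights the block is an exact identity, so inserting it never hurts
gradient flow.  The default inner width, min(16, C/16), keeps the whole
module at roughly one part in 750 of the backbone cost.
"""
from __future__ import annotations

from . import nn
from .flops import conv1d_spec, conv_spec
from .nn import Tensor, avg_pool2d, concat


class LMSM(nn.Module):
    def __init__(self, channels: int, inner: int | None = None, reduction: int | None = None,
                 dilations: tuple[int, ...] = (1, 2, 3, 4), local_pool: int = 2,
                 channel_kernel: int = 3):
        super().__init__()
        if reduction is not None:
            inner = channels // reduction
        if inner is None:
            inner = min(16, channels // 16)
        if inner <= 0 or inner % 4:
            raise ValueError(f"inner width {inner} must be a positive multiple of 4 "
                             f"(channels={channels})")
        if list(dilations) != sorted(set(dilations)) or min(dilations) < 1:
            raise ValueError("dilations must be strictly increasing positive integers")
        if len(dilations) != 4:
            raise ValueError("the multi-scale branch uses exactly 4 dilation groups")
        self.channels, self.inner = channels, inner
        self.dilations, self.local_pool = tuple(dilations), local_pool
        self.channel_kernel = channel_kernel
        self.down = nn.Conv2d(channels, inner, 1)
        self.branches = nn.Sequential(*[
            nn.Conv2d(inner // 4, inner // 4, 3, padding=d, dilation=d) for d in dilations])
        self.up = nn.Conv2d(inner, channels, 1)
        self.channel_conv = nn.Conv1d(1, 1, channel_kernel, padding=channel_kernel // 2)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        # branch 1: local pool -> global pool -> 1-D channel conv -> broadcast
        local = avg_pool2d(x, self.local_pool) if min(h, w) >= self.local_pool else x
        vec = local.mean(axis=(2, 3))                       # (N, C)
        vec = self.channel_conv(vec.reshape(n, 1, c)).reshape(n, c, 1, 1)
        gate = vec.sigmoid()

        # branch 2: reduce, 4-way dilated split, concat, restore
        z = self.down(x)
        g = self.inner // 4
        parts = [conv(z[:, i * g:(i + 1) * g]) for i, conv in enumerate(self.branches)]
        z = self.up(concat(parts, axis=1))
        return z * gate + x

    def flop_specs(self, in_shape):
        c, h, w = in_shape
        m = self.inner
        specs = [conv1d_spec("lmsm.channel_conv", self.channel_kernel, 1, 1, c),
                 conv_spec("lmsm.down", 1, c, m, h, w)]
        for d in self.dilations:
            specs.append(conv_spec(f"lmsm.dilated{d}", 3, m // 4, m // 4, h, w))
        specs.append(conv_spec("lmsm.up", 1, m, c, h, w))
        return specs, in_shape
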