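"""ResNet-AL backbone: ResNet34 stage layout with ABSM inside every
BasicBlock and an LMSM after each stage, emitting a three-level pyramid.

Stage layout (after a 7x7/2 stem plus 3x3/2 max-pool): block counts
(3, 4, 6, 3) at widths (64, 128, 256, 512) with strides (1, 2, 2, 2).  The
pyramid taps the outputs of stages 2/3/4 at strides 8/16/32, so a 640 input
yields c: 128x80x80, b: 256x40x40, a: 512x20x20.  ABSM sits on the residual
branch before the addition (squeeze-excitation convention); with its flag
off a block is the canonical ResNet34 BasicBlock.  Both attention flags
exist so the ablation chain (plain -> +ABSM -> +LMSM) is reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from . import nn
from .absm import ABSM
from .flops import conv_out_hw, conv_spec
from .lmsm import LMSM
from .nn import Tensor

STAGE_BLOCKS = (3, 4, 6, 3)
STAGE_CHANNELS = (64, 128, 256, 512)


@dataclass
class BackboneConfig:
    enable_absm: bool = True
    enable_lmsm: bool = True
    absm_heads: int = 4
    absm_compress_stride: int = 2
    absm_qkv_kernel: int = 7


@dataclass
class PyramidTriple:
    """Backbone outputs: a deepest (stride 32), b mid (16), c shallow (8)."""

    a: Tensor
    b: Tensor
    c: Tensor


class BasicBlock(nn.Module):
    def __init__(self, cin: int, cout: int, stride: int, cfg: BackboneConfig):
        super().__init__()
        self.cin, self.cout, self.stride = cin, cout, stride
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1)
        self.bn2 = nn.BatchNorm2d(cout)
        self.absm = ABSM(cout, heads=cfg.absm_heads,
                         compress_stride=cfg.absm_compress_stride,
                         qkv_kernel=cfg.absm_qkv_kernel) if cfg.enable_absm else None
        if stride != 1 or cin != cout:
            self.down = nn.Conv2d(cin, cout, 1, stride=stride)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down = None

    def forward(self, x: Tensor) -> Tensor:
        r = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        if self.absm is not None:
            r = self.absm(r)
        idt = self.down_bn(self.down(x)) if self.down is not None else x
        return (idt + r).relu()

    def flop_specs(self, in_shape):
        c, h, w = in_shape
        ho, wo = conv_out_hw(h, w, 3, self.stride, 1)
        specs = [conv_spec("block.conv1", 3, self.cin, self.cout, ho, wo),
                 conv_spec("block.conv2", 3, self.cout, self.cout, ho, wo)]
        if self.absm is not None:
            sub, _ = self.absm.flop_specs((self.cout, ho, wo))
            specs.extend(sub)
        if self.down is not None:
            specs.append(conv_spec("block.down", 1, self.cin, self.cout, ho, wo))
        return specs, (self.cout, ho, wo)


class ResNetAL(nn.Module):
    def __init__(self, cfg: BackboneConfig | None = None):
        super().__init__()
        cfg = cfg or BackboneConfig()
        self.cfg = cfg
        self.stem_conv = nn.Conv2d(3, 64, 7, stride=2, padding=3)
        self.stem_bn = nn.BatchNorm2d(64)
        self.pool = nn.MaxPool2d(3, 2, 1)
        cin = 64
        self.stages: list[nn.Sequential] = []
        self.lmsms: list[LMSM | None] = []
        for si, (n, c) in enumerate(zip(STAGE_BLOCKS, STAGE_CHANNELS)):
            blocks = []
            for bi in range(n):
                stride = 2 if (bi == 0 and si > 0) else 1
                blocks.append(BasicBlock(cin, c, stride, cfg))
                cin = c
            stage = nn.Sequential(*blocks)
            self._modules[f"stage{si + 1}"] = stage
            self.stages.append(stage)
            lm = LMSM(c) if cfg.enable_lmsm else None
            if lm is not None:
                self._modules[f"lmsm{si + 1}"] = lm
            self.lmsms.append(lm)

    def forward(self, x: Tensor) -> PyramidTriple:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial size {x.shape[2:]} must be divisible by 32")
        y = self.pool(self.stem_bn(self.stem_conv(x)).relu())
        taps = []
        for stage, lm in zip(self.stages, self.lmsms):
            y = stage(y)
            if lm is not None:
                y = lm(y)
            taps.append(y)
        return PyramidTriple(a=taps[3], b=taps[2], c=taps[1])

    def flop_specs(self, in_shape):
        c, h, w = in_shape
        ho, wo = conv_out_hw(h, w, 7, 2, 3)
        specs = [conv_spec("stem.conv", 7, 3, 64, ho, wo)]
        shape = (64, conv_out_hw(ho, wo, 3, 2, 1)[0], conv_out_hw(ho, wo, 3, 2, 1)[1])
        taps = []
        for si, (stage, lm) in enumerate(zip(self.stages, self.lmsms)):
            for bi, block in enumerate(stage):
                sub, shape = block.flop_specs(shape)
                specs.extend(_prefixed(sub, f"stage{si + 1}.{bi}"))
            if lm is not None:
                sub, shape = lm.flop_specs(shape)
                specs.extend(_prefixed(sub, f"stage{si + 1}"))
            taps.append(shape)
        return specs, (taps[3], taps[2], taps[1])     # (a, b, c) shapes


def _prefixed(specs, prefix):
    from dataclasses import replace
    return [replace(s, name=f"{prefix}.{s.name}") for s in specs]
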