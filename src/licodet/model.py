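"""Full detector assembly and the ablation presets.

The ablation chain mirrors the study design: a plain ResNet34 backbone with
the decoupled head ("resnet34-d"), plus ABSM in every BasicBlock
("resnet34-ad"), plus LMSM after every stage ("resnet34-ald"), plus the
progressive fusion neck ("alpd-net").
"""
from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .backbone import BackboneConfig, ResNetAL
from .head import DetectHead, HEAD_WIDTHS, STRIDES
from .nn import Tensor
from .pffm import PFFM

PRESETS = {
    "resnet34-d": dict(enable_absm=False, enable_lmsm=False, enable_pffm=False),
    "resnet34-ad": dict(enable_absm=True, enable_lmsm=False, enable_pffm=False),
    "resnet34-ald": dict(enable_absm=True, enable_lmsm=True, enable_pffm=False),
    "alpd-net": dict(enable_absm=True, enable_lmsm=True, enable_pffm=True),
}


@dataclass
class ModelConfig:
    enable_absm: bool = True
    enable_lmsm: bool = True
    enable_pffm: bool = True
    n_classes: int = 3
    head_widths: tuple[int, int, int] = HEAD_WIDTHS
    init_seed: int = 0

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "ModelConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(**{**PRESETS[name], **overrides})

    @property
    def preset_name(self) -> str:
        flags = (self.enable_absm, self.enable_lmsm, self.enable_pffm)
        for name, kw in PRESETS.items():
            if (kw["enable_absm"], kw["enable_lmsm"], kw["enable_pffm"]) == flags:
                return name
        return "custom"


class Detector(nn.Module):
    """Backbone + (optional) fusion neck + decoupled head."""

    def __init__(self, config: ModelConfig | str = "alpd-net"):
        super().__init__()
        if isinstance(config, str):
            config = ModelConfig.from_preset(config)
        self.config = config
        with nn.init_seed(config.init_seed):
            self.backbone = ResNetAL(BackboneConfig(enable_absm=config.enable_absm,
                                                    enable_lmsm=config.enable_lmsm))
            self.pffm = PFFM() if config.enable_pffm else None
            self.head = DetectHead(widths=tuple(config.head_widths),
                                   n_classes=config.n_classes)

    def forward(self, images: Tensor) -> list[tuple[Tensor, Tensor]]:
        """(N,3,H,W) float input -> per-scale (box, cls) maps, strides 8/16/32."""
        p = self.backbone(images)
        if self.pffm is not None:
            fused = self.pffm(p.a, p.b, p.c)
            feats = [fused.C, fused.B, fused.A]
        else:
            feats = [p.c, p.b, p.a]
        return self.head(feats)

    def flop_specs(self, in_shape):
        specs, (sa, sb, sc) = self.backbone.flop_specs(in_shape)
        if self.pffm is not None:
            sub, _ = self.pffm.flop_specs((sa, sb, sc))
            specs = specs + sub
        head_specs, _ = self.head.flop_specs([sc, sb, sa])
        return specs + head_specs, None

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str) -> None:
        arrays = self.state_dict()
        np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
        with open(os.path.splitext(path)[0] + ".config.json", "w") as f:
            json.dump(asdict(self.config), f, indent=2)

    @classmethod
    def load(cls, path: str) -> "Detector":
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".config.json") as f:
            cfg = json.load(f)
        cfg["head_widths"] = tuple(cfg["head_widths"])
        model = cls(ModelConfig(**cfg))
        data = np.load(base + ".npz")
        model.load_state_dict({k: data[k] for k in data.files})
        return model


def preprocess(images: np.ndarray) -> Tensor:
    """uint8 (N,H,W,3) or (H,W,3) -> normalised float32 (N,3,H,W) tensor."""
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    x = arr.astype(np.float32) / 255.0
    x = (x - 0.5) / 0.25
    return Tensor(np.ascontiguousarray(x.transpose(0, 3, 1, 2)))
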