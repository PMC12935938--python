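"""Full segmentation models: PSPNet and its attention / lightweight variants.

The forward pipeline is backbone -> (optional attention) -> pyramid pooling
-> classifier -> bilinear upsample to input resolution -> per-pixel
softmax.  The pyramid pooling module (PPM) average-pools the C-channel
feature map to each scale S in {1, 2, 3, 6}, reduces each pooled map to
C/len(scales) channels with a 1x1 conv, upsamples back, and concatenates
with the input map (2C channels total) before a fusion conv.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .attention import AttentionSpec, build_attention
from .backbones import BackboneSpec, build_backbone
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = [
    "ModelSpec",
    "Prediction",
    "PyramidPooling",
    "SegModel",
    "assemble_model",
    "predict",
    "ppm_forward",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelSpec:
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    attention: AttentionSpec = field(default_factory=AttentionSpec)
    ppm_scales: tuple[int, ...] = (1, 2, 3, 6)
    num_classes: int = 2
    aux_head: bool = False

    def __post_init__(self):
        scales = tuple(self.ppm_scales)
        if any(s <= 0 for s in scales) or any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError(f"ppm_scales must be strictly increasing positive integers, got {scales}")
        self.ppm_scales = scales
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        bb = {k: v for k, v in d.get("backbone", {}).items() if k in ("name", "output_stride")}
        att = d.get("attention", {})
        return cls(
            backbone=BackboneSpec(**bb),
            attention=AttentionSpec(**att),
            ppm_scales=tuple(d.get("ppm_scales", (1, 2, 3, 6))),
            num_classes=d.get("num_classes", 2),
            aux_head=d.get("aux_head", False),
        )


@dataclass
class Prediction:
    """Per-pixel class probabilities (num_classes, H, W) and the argmax mask."""

    prob: np.ndarray
    mask: np.ndarray


class PyramidPooling(nn.Module):
    """Multi-scale context aggregation; output width is in_channels // 4."""

    def __init__(self, in_channels: int, scales: tuple[int, ...] = (1, 2, 3, 6)):
        super().__init__()
        self.scales = tuple(scales)
        branch_ch = in_channels // len(self.scales)
        self.branches = [
            nn.Sequential(nn.Conv2d(in_channels, branch_ch, 1, bias=False), nn.BatchNorm2d(branch_ch), nn.ReLU())
            for _ in self.scales
        ]
        concat_ch = in_channels + branch_ch * len(self.scales)
        self.out_channels = in_channels // 4
        self.fuse = nn.Sequential(
            nn.Conv2d(concat_ch, self.out_channels, 3, padding=1, bias=False),
            nn.BatchNorm2d(self.out_channels),
            nn.ReLU(),
        )

    def forward(self, x: Tensor, return_concat: bool = False):
        H, W = x.shape[2], x.shape[3]
        if H < max(self.scales) or W < max(self.scales):
            raise ValueError(
                f"feature map {H}x{W} is smaller than the largest pooling scale {max(self.scales)}"
            )
        maps = [x]
        for scale, branch in zip(self.scales, self.branches):
            pooled = F.adaptive_avg_pool2d(x, scale)
            maps.append(F.interpolate_bilinear(branch(pooled), (H, W)))
        cat = concat(maps, axis=1)
        fused = self.fuse(cat)
        return (fused, cat) if return_concat else fused


def ppm_forward(fmap: np.ndarray, scales: tuple[int, ...] = (1, 2, 3, 6),
                module: PyramidPooling | None = None, return_concat: bool = False):
    """Apply pyramid pooling to a (C, H, W) array; convenience wrapper."""
    module = module or PyramidPooling(fmap.shape[0], scales)
    out = module(Tensor(np.asarray(fmap, dtype=np.float32)[None]), return_concat=return_concat)
    if return_concat:
        fused, cat = out
        return fused.data[0], cat.data[0]
    return out.data[0]


class SegModel(nn.Module):
    """Backbone + optional attention + PPM + classifier, softmax output."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        self.backbone = build_backbone(spec.backbone)
        self.attention = build_attention(spec.backbone.out_channels, spec.attention)
        self.ppm = PyramidPooling(spec.backbone.out_channels, spec.ppm_scales)
        self.classifier = nn.Conv2d(self.ppm.out_channels, spec.num_classes, 1)
        if spec.aux_head:
            aux_ch = spec.backbone.aux_channels
            self.aux = nn.Sequential(
                nn.Conv2d(aux_ch, aux_ch // 4, 3, padding=1, bias=False),
                nn.BatchNorm2d(aux_ch // 4),
                nn.ReLU(),
                nn.Conv2d(aux_ch // 4, spec.num_classes, 1),
            )
        else:
            self.aux = None

    def forward(self, x: Tensor, return_aux: bool = False):
        size = (x.shape[2], x.shape[3])
        if self.aux is not None:
            feat, aux_feat = self.backbone(x, return_aux=True)
        else:
            feat = self.backbone(x)
        feat = self.attention(feat)
        logits = self.classifier(self.ppm(feat))
        logits = F.interpolate_bilinear(logits, size)
        if return_aux and self.aux is not None:
            aux_logits = F.interpolate_bilinear(self.aux(aux_feat), size)
            return logits, aux_logits
        return logits


def assemble_model(spec: ModelSpec) -> SegModel:
    return SegModel(spec)


def predict(model: SegModel, image: np.ndarray) -> Prediction:
    """Segment one (3, H, W) image in [0, 1]; deterministic in eval mode."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) image, got shape {image.shape}")
    was_training = model.training
    model.eval()
    logits = model(Tensor(image[None]))
    prob = logits.softmax(axis=1).data[0]
    if was_training:
        model.train()
    return Prediction(prob=prob, mask=prob.argmax(axis=0).astype(np.uint8))


# ---------------------------------------------------------------------------
# checkpoints: npz archive with the ModelSpec embedded as JSON
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = {k.replace("/", "_"): v for k, v in model.state_dict().items()}
    np.savez(path, __model_spec__=np.array(json.dumps(model.spec.to_dict())), **state)
    return path


def load_checkpoint(path: str | Path) -> SegModel:
    with np.load(path, allow_pickle=False) as archive:
        spec = ModelSpec.from_dict(json.loads(str(archive["__model_spec__"])))
        model = SegModel(spec)
        state = {k: archive[k] for k in archive.files if k != "__model_spec__"}
    model.load_state_dict(state)
    return model
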