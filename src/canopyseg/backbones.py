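"""Backbone feature extractors: ResNet-50 and MobileNetV3-Large.

Both map an RGB batch (N, 3, H, W) to a deep feature map of spatial size
ceil(input / output_stride).  Strides beyond the requested output stride
are converted to dilation (the standard dilated-FCN trick), so the
advertised channel width (2048 for ResNet-50, 960 for MobileNetV3-Large)
is reached without shrinking the map further.  Weights are randomly
initialised; there is no pretrained download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["BackboneSpec", "build_backbone", "parameter_count", "ResNet50", "MobileNetV3Large"]

_WIDTHS = {"resnet50": 2048, "mobilenetv3": 960}
_AUX = {"resnet50": 1024, "mobilenetv3": 112}


@dataclass
class BackboneSpec:
    name: str = "resnet50"
    output_stride: int = 8
    out_channels: int = field(init=False)
    aux_channels: int = field(init=False)

    def __post_init__(self):
        if self.name not in _WIDTHS:
            raise ValueError(f"unknown backbone {self.name!r}; supported: {sorted(_WIDTHS)}")
        if self.output_stride not in (8, 16):
            raise ValueError(f"output_stride must be 8 or 16, got {self.output_stride}")
        self.out_channels = _WIDTHS[self.name]
        self.aux_channels = _AUX[self.name]


def _conv_bn(in_ch: int, out_ch: int, kernel: int, stride: int = 1, dilation: int = 1,
             act: type[nn.Module] = nn.ReLU) -> nn.Sequential:
    pad = (kernel // 2) * dilation
    return nn.Sequential(
        nn.Conv2d(in_ch, out_ch, kernel, stride=stride, padding=pad, dilation=dilation, bias=False),
        nn.BatchNorm2d(out_ch),
        act(),
    )


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch: int, planes: int, stride: int = 1, dilation: int = 1):
        super().__init__()
        out_ch = planes * self.expansion
        self.conv1 = nn.Conv2d(in_ch, planes, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3, stride=stride, padding=dilation, dilation=dilation, bias=False)
        self.bn2 = nn.BatchNorm2d(planes)
        self.conv3 = nn.Conv2d(planes, out_ch, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False), nn.BatchNorm2d(out_ch))
        else:
            self.down = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        shortcut = self.down(x) if self.down is not None else x
        return (y + shortcut).relu()


class ResNet50(nn.Module):
    """ResNet-50 trunk (no classification head), dilated to the output stride."""

    def __init__(self, output_stride: int = 8):
        super().__init__()
        self.output_stride = output_stride
        self.out_channels = 2048
        self.aux_channels = 1024
        if output_stride == 8:
            strides, dilations = (1, 2, 1, 1), (1, 1, 2, 4)
        else:  # 16
            strides, dilations = (1, 2, 2, 1), (1, 1, 1, 2)
        self.stem = _conv_bn(3, 64, 7, stride=2)
        blocks_per_layer = (3, 4, 6, 3)
        planes = (64, 128, 256, 512)
        in_ch = 64
        self.layers = []
        for n_blocks, p, s, d in zip(blocks_per_layer, planes, strides, dilations):
            blocks = [_Bottleneck(in_ch, p, stride=s, dilation=d)]
            in_ch = p * _Bottleneck.expansion
            blocks += [_Bottleneck(in_ch, p, dilation=d) for _ in range(n_blocks - 1)]
            self.layers.append(nn.Sequential(*blocks))

    def forward(self, x: Tensor, return_aux: bool = False):
        y = self.stem(x)
        y = F.max_pool2d(y, 3, 2, 1)
        y = self.layers[0](y)
        y = self.layers[1](y)
        aux = self.layers[2](y)
        out = self.layers[3](aux)
        return (out, aux) if return_aux else out


class _SqueezeExcite(nn.Module):
    def __init__(self, channels: int, se_channels: int):
        super().__init__()
        self.fc1 = nn.Conv2d(channels, se_channels, 1)
        self.fc2 = nn.Conv2d(se_channels, channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        s = F.global_avg_pool(x)
        s = self.fc2(self.fc1(s).relu()).hardsigmoid()
        return x * s


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


class _InvertedResidual(nn.Module):
    def __init__(self, in_ch: int, exp: int, out_ch: int, kernel: int, stride: int,
                 dilation: int, use_se: bool, use_hs: bool):
        super().__init__()
        act = nn.Hardswish if use_hs else nn.ReLU
        self.use_res = stride == 1 and in_ch == out_ch
        layers: list[nn.Module] = []
        if exp != in_ch:
            layers.append(_conv_bn(in_ch, exp, 1, act=act))
        layers.append(
            nn.Sequential(
                nn.Conv2d(exp, exp, kernel, stride=stride, padding=(kernel // 2) * dilation,
                          dilation=dilation, groups=exp, bias=False),
                nn.BatchNorm2d(exp),
                act(),
            )
        )
        if use_se:
            layers.append(_SqueezeExcite(exp, _make_divisible(exp // 4)))
        layers.append(nn.Sequential(nn.Conv2d(exp, out_ch, 1, bias=False), nn.BatchNorm2d(out_ch)))
        self.body = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        y = self.body(x)
        return y + x if self.use_res else y


# (kernel, expansion, out, SE, hardswish, stride)
_MBV3_LARGE = [
    (3, 16, 16, False, False, 1),
    (3, 64, 24, False, False, 2),
    (3, 72, 24, False, False, 1),
    (5, 72, 40, True, False, 2),
    (5, 120, 40, True, False, 1),
    (5, 120, 40, True, False, 1),
    (3, 240, 80, False, True, 2),
    (3, 200, 80, False, True, 1),
    (3, 184, 80, False, True, 1),
    (3, 184, 80, False, True, 1),
    (3, 480, 112, True, True, 1),
    (3, 672, 112, True, True, 1),
    (5, 672, 160, True, True, 2),
    (5, 960, 160, True, True, 1),
    (5, 960, 160, True, True, 1),
]
_MBV3_AUX_INDEX = 11  # feature after the last 112-channel block


class MobileNetV3Large(nn.Module):
    """MobileNetV3-Large trunk, strides past the output stride become dilation."""

    def __init__(self, output_stride: int = 16):
        super().__init__()
        self.output_stride = output_stride
        self.out_channels = 960
        self.aux_channels = 112
        self.stem = _conv_bn(3, 16, 3, stride=2, act=nn.Hardswish)
        current_stride, dilation = 2, 1
        self.blocks = []
        in_ch = 16
        for kernel, exp, out_ch, use_se, use_hs, stride in _MBV3_LARGE:
            if stride > 1 and current_stride * stride > output_stride:
                block_stride, dilation = 1, dilation * stride
            else:
                block_stride = stride
                current_stride *= stride
            self.blocks.append(_InvertedResidual(in_ch, exp, out_ch, kernel, block_stride, dilation, use_se, use_hs))
            in_ch = out_ch
        self.final = _conv_bn(in_ch, 960, 1, act=nn.Hardswish)

    def forward(self, x: Tensor, return_aux: bool = False):
        y = self.stem(x)
        aux = None
        for i, block in enumerate(self.blocks):
            y = block(y)
            if i == _MBV3_AUX_INDEX:
                aux = y
        out = self.final(y)
        return (out, aux) if return_aux else out


def build_backbone(spec: BackboneSpec) -> nn.Module:
    """Build the feature extractor named by ``spec``; raises for unknown names."""
    if spec.name == "resnet50":
        return ResNet50(spec.output_stride)
    if spec.name == "mobilenetv3":
        return MobileNetV3Large(spec.output_stride)
    raise ValueError(f"unknown backbone {spec.name!r}; supported: {sorted(_WIDTHS)}")


def parameter_count(module: nn.Module) -> int:
    """Exact number of learnable scalars in a built extractor or model."""
    return nn.parameter_count(module)
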