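"""Analytic layer descriptions of two standard lightweight baselines.

These exist purely to validate the parameter/MAC counters against published
efficiency figures; no weights are ever instantiated. Both descriptions
follow the reference implementations (ImageNet variants, 1000-class heads,
bias-free convolutions paired with batch norm).
"""

from __future__ import annotations

from .profiling import LayerSpec, ProfileReport, conv_out_size

__all__ = ["mobilenet_v2_profile", "efficientnet_b0_profile"]

# (expansion, out channels, repeats, first stride) per MobileNetV2 stage
_MBV2_STAGES = [
    (1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
    (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1),
]

# (expansion, out channels, repeats, first stride, kernel) per EfficientNet-B0 stage
_EFFB0_STAGES = [
    (1, 16, 1, 1, 3), (6, 24, 2, 2, 3), (6, 40, 2, 2, 5), (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5), (6, 192, 4, 2, 5), (6, 320, 1, 1, 3),
]


class _Builder:
    def __init__(self, input_size: int):
        self.h = input_size
        self.specs: list[LayerSpec] = []

    def conv_bn(self, name, cin, cout, k, stride=1, groups=1):
        self.h = conv_out_size(self.h, k, stride)
        self.specs.append(LayerSpec(f"{name}.conv", "conv", cin, cout, k, stride,
                                    groups=groups, bias=False, out_h=self.h, out_w=self.h))
        self.specs.append(LayerSpec(f"{name}.bn", "bn", cout=cout))

    def conv1x1_biased(self, name, cin, cout):
        # squeeze-excitation convs act on a pooled 1x1 map
        self.specs.append(LayerSpec(name, "conv", cin, cout, 1, bias=True,
                                    out_h=1, out_w=1))


def mobilenet_v2_profile(input_size: int = 224) -> ProfileReport:
    """Standard MobileNetV2 (width multiplier 1.0, 1000-class head)."""
    b = _Builder(input_size)
    b.conv_bn("stem", 3, 32, 3, 2)
    cin = 32
    for t, c, n, s in _MBV2_STAGES:
        for i in range(n):
            stride = s if i == 0 else 1
            hidden = cin * t
            pre = f"ir{c}.{i}"
            if t != 1:
                b.conv_bn(f"{pre}.expand", cin, hidden, 1)
            b.conv_bn(f"{pre}.dw", hidden, hidden, 3, stride, groups=hidden)
            b.conv_bn(f"{pre}.project", hidden, c, 1)
            cin = c
    b.conv_bn("final", cin, 1280, 1)
    b.specs.append(LayerSpec("classifier", "linear", 1280, 1000))
    return ProfileReport(b.specs, input_size)


def efficientnet_b0_profile(input_size: int = 224) -> ProfileReport:
    """Standard EfficientNet-B0 (1000-class head, squeeze-excitation blocks)."""
    b = _Builder(input_size)
    b.conv_bn("stem", 3, 32, 3, 2)
    cin = 32
    for t, c, n, s, k in _EFFB0_STAGES:
        for i in range(n):
            stride = s if i == 0 else 1
            hidden = cin * t
            pre = f"mb{c}.{i}"
            if t != 1:
                b.conv_bn(f"{pre}.expand", cin, hidden, 1)
            b.conv_bn(f"{pre}.dw", hidden, hidden, k, stride, groups=hidden)
            squeeze = max(1, cin // 4)
            b.conv1x1_biased(f"{pre}.se.reduce", hidden, squeeze)
            b.conv1x1_biased(f"{pre}.se.expand", squeeze, hidden)
            b.conv_bn(f"{pre}.project", hidden, c, 1)
            cin = c
    b.conv_bn("final", cin, 1280, 1)
    b.specs.append(LayerSpec("classifier", "linear", 1280, 1000))
    return ProfileReport(b.specs, input_size)
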