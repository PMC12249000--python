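"""Analytic parameter and multiply-accumulate accounting.

Counting conventions
--------------------
* parameters: conv = C_out * C_in * k^2 / groups (+ C_out biases);
  batch norm = 2C; linear = in * out (+ out biases).
* MACs: conv = H_out * W_out * C_out * C_in * k^2 / groups;
  linear = in * out per invocation. Batch norm, pooling, activations, and
  element-wise attention multiplications are excluded. One MAC is reported
  as one FLOP.
* headline figures follow the efficiency-table convention of the lightweight
  CNN literature: the parameter figure counts convolution and linear weights
  (normalization affine terms excluded) and is truncated at one decimal in
  millions, which is the convention under which the standard MobileNetV2
  (3,470,760 conv+linear weights) is printed as "3.4 M"; the FLOP figure is
  total MACs rounded to two decimals in G.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import ModelConfig
from .model import CellSage


@dataclass
class LayerSpec:
    """One weight-bearing layer, sufficient for analytic counting."""

    name: str
    kind: str  # 'conv' | 'bn' | 'linear'
    cin: int = 0
    cout: int = 0
    k: int = 1
    stride: int = 1
    groups: int = 1
    bias: bool = True
    out_h: int = 0
    out_w: int = 0
    calls: int = 1  # >1 when the same weights are applied repeatedly

    @property
    def n_params(self) -> int:
        if self.kind == "conv":
            return self.cout * self.cin * self.k * self.k // self.groups \
                + (self.cout if self.bias else 0)
        if self.kind == "bn":
            return 2 * self.cout
        if self.kind == "linear":
            return self.cin * self.cout + (self.cout if self.bias else 0)
        raise ValueError(f"unknown layer kind {self.kind!r}")

    @property
    def n_macs(self) -> int:
        if self.kind == "conv":
            return (self.out_h * self.out_w * self.cout * self.cin
                    * self.k * self.k // self.groups) * self.calls
        if self.kind == "linear":
            return self.cin * self.cout * self.calls
        return 0


@dataclass
class ProfileReport:
    """Per-layer and total parameter/MAC accounting."""

    per_layer: list[LayerSpec]
    input_size: int

    @property
    def total_params(self) -> int:
        return sum(l.n_params for l in self.per_layer)

    @property
    def weight_params(self) -> int:
        """Convolution + linear parameters (normalization affine excluded)."""
        return sum(l.n_params for l in self.per_layer if l.kind != "bn")

    @property
    def total_macs(self) -> int:
        return sum(l.n_macs for l in self.per_layer)

    @property
    def params_millions(self) -> float:
        """Headline figure: weight params, truncated at one decimal."""
        return math.floor(self.weight_params / 1e5) / 10.0

    @property
    def gflops(self) -> float:
        """Headline figure: MACs in G, rounded to two decimals (1 MAC = 1 FLOP)."""
        return round(self.total_macs / 1e9, 2)

    def rows(self):
        for l in self.per_layer:
            yield (l.name, l.n_params, l.n_macs)

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "total_params": self.total_params,
            "weight_params": self.weight_params,
            "total_macs": self.total_macs,
            "params_millions": self.params_millions,
            "gflops": self.gflops,
            "per_layer": [
                {"name": n, "params": p, "macs": m} for n, p, m in self.rows()
            ],
        }


def conv_out_size(h: int, k: int, stride: int) -> int:
    """Output length for 'same' (k // 2) zero padding."""
    p = k // 2
    return (h + 2 * p - k) // stride + 1


def layer_specs(config: ModelConfig, input_size: int | None = None) -> list[LayerSpec]:
    """Mirror the network construction layer-for-layer."""
    config.validate()
    size = config.input_size if input_size is None else input_size
    specs: list[LayerSpec] = []
    h = conv_out_size(size, 3, config.mscfe_stride)
    cat = config.mscfe_out_channels
    if config.variant == "no_mscfe":
        specs.append(LayerSpec("mscfe.conv3x3", "conv", config.input_channels, cat,
                               3, config.mscfe_stride, out_h=h, out_w=h))
    else:
        for k in config.mscfe_kernels:
            hk = conv_out_size(size, k, config.mscfe_stride)
            specs.append(LayerSpec(f"mscfe.conv{k}x{k}", "conv", config.input_channels,
                                   config.mscfe_branch_channels, k, config.mscfe_stride,
                                   out_h=hk, out_w=hk))
    cin = cat
    for si, width in enumerate(config.stage_widths):
        for bi in range(config.blocks_per_stage):
            stride = 2 if bi == 0 else 1
            h = conv_out_size(h, 3, stride)
            pre = f"stage{si}.block{bi}"
            specs.append(LayerSpec(f"{pre}.dw", "conv", cin, cin, 3, stride,
                                   groups=cin, out_h=h, out_w=h))
            specs.append(LayerSpec(f"{pre}.bn", "bn", cout=cin))
            specs.append(LayerSpec(f"{pre}.pw", "conv", cin, width, 1, out_h=h, out_w=h))
            cin = width
    if config.variant != "no_cbam":
        hidden = cin // config.cbam_reduction_ratio
        # shared MLP applied to both pooled descriptors -> two invocations
        specs.append(LayerSpec("cbam.cam.fc1", "linear", cin, hidden, calls=2))
        specs.append(LayerSpec("cbam.cam.fc2", "linear", hidden, cin, calls=2))
        specs.append(LayerSpec("cbam.sam.conv", "conv", 2, 1, config.spatial_kernel,
                               out_h=h, out_w=h))
    specs.append(LayerSpec("head.fc", "linear", cin, 1))
    return specs


def count_parameters(target: ModelConfig | CellSage) -> ProfileReport:
    """Analytic parameter counts; exact for the instantiated network."""
    config = target.config if isinstance(target, CellSage) else target
    report = ProfileReport(layer_specs(config), config.input_size)
    if isinstance(target, CellSage):
        enumerated = target.num_parameters()
        if report.total_params != enumerated:
            raise AssertionError(
                f"analytic total {report.total_params} != enumerated {enumerated}")
    return report


def count_macs(target: ModelConfig | CellSage, input_size: int | None = None) -> ProfileReport:
    """Analytic multiply-accumulate counts for one forward pass."""
    config = target.config if isinstance(target, CellSage) else target
    size = config.input_size if input_size is None else input_size
    return ProfileReport(layer_specs(config, size), size)
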