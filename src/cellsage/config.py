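"""Architectural configuration and its validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

VARIANTS = ("full", "no_cbam", "no_mscfe")


class ConfigError(ValueError):
    """Raised when a configuration field violates its invariants."""


@dataclass
class ModelConfig:
    """Every architectural hyperparameter of the network.

    The defaults are the frozen reference configuration, calibrated with the
    analytic profiler so that the total parameter budget reports as 3.8 M and
    the multiply-accumulate budget at 224 x 224 input reports as 0.49 G.
    """

    input_channels: int = 3
    input_size: int = 224
    mscfe_branch_channels: int = 32
    mscfe_kernels: tuple[int, ...] = (7, 5, 3)
    mscfe_stride: int = 2
    stage_widths: tuple[int, ...] = (128, 224, 544, 1472)
    blocks_per_stage: int = 2
    cbam_reduction_ratio: int = 16
    spatial_kernel: int = 7
    dropout_rate: float = 0.2
    variant: str = "full"

    def __post_init__(self):
        self.mscfe_kernels = tuple(self.mscfe_kernels)
        self.stage_widths = tuple(self.stage_widths)
        self.validate()

    # -- invariants ----------------------------------------------------------
    def validate(self) -> None:
        if self.input_channels < 1:
            raise ConfigError(f"input_channels must be >= 1, got {self.input_channels}")
        if self.input_size < 1:
            raise ConfigError(f"input_size must be >= 1, got {self.input_size}")
        if self.mscfe_branch_channels < 1:
            raise ConfigError("mscfe_branch_channels must be >= 1, got "
                              f"{self.mscfe_branch_channels}")
        for k in (*self.mscfe_kernels, self.spatial_kernel):
            if k < 1 or k % 2 == 0:
                raise ConfigError(f"kernel sizes must be odd and positive, got {k}")
        if self.mscfe_stride < 1:
            raise ConfigError(f"mscfe_stride must be >= 1, got {self.mscfe_stride}")
        if not self.stage_widths or any(w < 1 for w in self.stage_widths):
            raise ConfigError(f"stage_widths must be positive, got {self.stage_widths}")
        if self.blocks_per_stage < 1:
            raise ConfigError(f"blocks_per_stage must be >= 1, got {self.blocks_per_stage}")
        if self.cbam_reduction_ratio < 1:
            raise ConfigError("cbam_reduction_ratio must be >= 1, got "
                              f"{self.cbam_reduction_ratio}")
        if self.variant != "no_cbam" and self.stage_widths[-1] % self.cbam_reduction_ratio:
            raise ConfigError(
                f"cbam_reduction_ratio={self.cbam_reduction_ratio} must divide the "
                f"attended channel count {self.stage_widths[-1]}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    # -- derived quantities --------------------------------------------------
    @property
    def mscfe_out_channels(self) -> int:
        """Concatenated multi-scale output width (= branches x branch width)."""
        return len(self.mscfe_kernels) * self.mscfe_branch_channels

    def with_variant(self, variant: str) -> "ModelConfig":
        return dataclasses.replace(self, variant=variant)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mscfe_kernels"] = list(self.mscfe_kernels)
        d["stage_widths"] = list(self.stage_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def reference_config(**overrides) -> ModelConfig:
    """The frozen, budget-calibrated reference configuration."""
    ref = Path(__file__).with_name("reference_config.yaml")
    cfg = ModelConfig.load(ref)
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg
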