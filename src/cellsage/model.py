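"""The CellSage network.

Layer sequence: multi-scale feature extractor -> depthwise-separable stack
-> CBAM (channel then spatial attention) -> global average pool -> dropout
-> single-logit linear head. Built entirely on the NumPy layers in
:mod:`cellsage.nn` so that forward, backward, and Grad-CAM are available
without a deep-learning framework.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import VARIANTS, ConfigError, ModelConfig
from .nn import (BatchNorm2d, Conv2d, Dropout, GlobalAvgPool, Linear, Module,
                 ReLU, Sequential, sigmoid)

ROLES = ("input_x", "f_mscfe", "f_dwb", "f_prime", "f_double_prime")


@dataclass
class FeatureMap:
    """A (batched) C x H x W activation tensor with a pipeline-role tag."""

    values: np.ndarray
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.values.ndim == 3:
            self.values = self.values[None]
        if self.values.ndim != 4:
            raise ValueError("FeatureMap expects (C,H,W) or (N,C,H,W) values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap values must be finite")

    @property
    def channels(self) -> int:
        return self.values.shape[1]


@dataclass
class AttentionMaps:
    """Channel gate in (0,1)^C and spatial gate in (0,1)^(H x W)."""

    channel_map: np.ndarray | None = None
    spatial_map: np.ndarray | None = None

    def __post_init__(self):
        for m in (self.channel_map, self.spatial_map):
            if m is not None and (np.any(m <= 0.0) or np.any(m >= 1.0)):
                raise ValueError("attention values must lie strictly in (0, 1)")


class MSCFE(Module):
    """Parallel 7x7 / 5x5 / 3x3 convolutions on the same input, concatenated.

    Branch outputs are concatenated along the channel axis in kernel order.
    """

    def __init__(self, cfg: ModelConfig, name="mscfe"):
        super().__init__(name)
        self.branches = [
            Conv2d(cfg.input_channels, cfg.mscfe_branch_channels, k,
                   stride=cfg.mscfe_stride, name=f"{name}.conv{k}x{k}")
            for k in cfg.mscfe_kernels
        ]
        self.acts = [ReLU() for _ in self.branches]

    def children(self):
        return iter(self.branches)

    def forward(self, x, train=False):
        outs = [act.forward(b.forward(x, train), train)
                for b, act in zip(self.branches, self.acts)]
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dout):
        dx = None
        start = 0
        for b, act, w in zip(self.branches, self.acts, self._widths):
            d = b.backward(act.backward(dout[:, start:start + w]))
            dx = d if dx is None else dx + d
            start += w
        return dx


class DWBlock(Module):
    """Depthwise 3x3 -> BatchNorm -> ReLU -> pointwise 1x1 -> ReLU -> dropout."""

    def __init__(self, cin, cout, stride, dropout_rate, name="dwb"):
        super().__init__(name)
        self.dw = Conv2d(cin, cin, 3, stride=stride, groups=cin, name=f"{name}.dw")
        self.bn = BatchNorm2d(cin, name=f"{name}.bn")
        self.act1 = ReLU()
        self.pw = Conv2d(cin, cout, 1, name=f"{name}.pw")
        self.act2 = ReLU()
        self.drop = Dropout(dropout_rate, name=f"{name}.drop")
        self.seq = Sequential([self.dw, self.bn, self.act1, self.pw, self.act2, self.drop])

    def children(self):
        return iter([self.dw, self.bn, self.pw, self.drop])

    def forward(self, x, train=False):
        return self.seq.forward(x, train)

    def backward(self, dout):
        return self.seq.backward(dout)


class ChannelAttention(Module):
    """Channel gate: sigmoid(MLP(maxpool) + MLP(avgpool)), one shared MLP.

    The shared two-layer perceptron maps C -> C/r -> C with a ReLU between
    layers and is applied identically to both pooled descriptors.
    """

    def __init__(self, channels, reduction, name="cam"):
        super().__init__(name)
        if channels % reduction:
            raise ConfigError(
                f"reduction ratio {reduction} must divide channel count {channels}")
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, name=f"{name}.fc1")
        self.fc2 = Linear(hidden, channels, name=f"{name}.fc2")
        self.channels = channels

    def children(self):
        return iter([self.fc1, self.fc2])

    def init_weights(self, rng):
        self.fc1.init_weights(rng)
        self.fc2.init_weights(rng)

    def _mlp(self, v):
        h = self.fc1.forward(v)
        hr = np.maximum(h, 0)
        return self.fc2.forward(hr), (v, h)

    def forward(self, x, train=False):
        att, out = self.attend(x, train)
        return out

    def attend(self, x, train=False):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._argmax = flat.argmax(axis=2)
        mx = flat.max(axis=2)
        av = flat.mean(axis=2)
        # shared MLP, two invocations; caches rebuilt per branch in backward
        h1_mx = self.fc1.forward(mx)
        o_mx = self.fc2.forward(np.maximum(h1_mx, 0))
        h1_av = self.fc1.forward(av)
        o_av = self.fc2.forward(np.maximum(h1_av, 0))
        # clamp away from {0, 1}: the gate is mathematically open but float
        # sigmoids saturate for large logits
        att = np.clip(sigmoid(o_mx + o_av), 1e-7, 1.0 - 1e-7)
        out = x * att[:, :, None, None]
        self._cache = (x, mx, av, h1_mx, h1_av, att)
        return att, out

    def backward(self, dout):
        x, mx, av, h1_mx, h1_av, att = self._cache
        n, c, h, w = x.shape
        dx = dout * att[:, :, None, None]
        datt = (dout * x).sum(axis=(2, 3))
        dlogit = datt * att * (1.0 - att)

        def mlp_back(do, v, h1):
            self.fc2._x = np.maximum(h1, 0)
            dh = self.fc2.backward(do)
            dh = np.where(h1 > 0, dh, 0)
            self.fc1._x = v
            return self.fc1.backward(dh)

        dmx = mlp_back(dlogit, mx, h1_mx)
        dav = mlp_back(dlogit, av, h1_av)
        # avg-pool backward: uniform spread; max-pool backward: scatter to argmax
        dx = dx + dav[:, :, None, None] / (h * w)
        dflat = np.zeros((n, c, h * w), dtype=np.float32)
        np.put_along_axis(dflat, self._argmax[:, :, None], dmx[:, :, None], axis=2)
        dx = dx + dflat.reshape(n, c, h, w)
        return dx.astype(np.float32, copy=False)


class SpatialAttention(Module):
    """Spatial gate: sigmoid(conv7x7(concat(channel-max, channel-avg)))."""

    def __init__(self, kernel=7, name="sam"):
        super().__init__(name)
        self.conv = Conv2d(2, 1, kernel, name=f"{name}.conv")

    def children(self):
        return iter([self.conv])

    def init_weights(self, rng):
        self.conv.init_weights(rng)

    def forward(self, x, train=False):
        att, out = self.attend(x, train)
        return out

    def attend(self, x, train=False):
        n, c, h, w = x.shape
        self._argmax = x.argmax(axis=1)
        mx = x.max(axis=1)
        av = x.mean(axis=1)
        cat = np.stack([mx, av], axis=1)
        z = self.conv.forward(cat)
        att = np.clip(sigmoid(z), 1e-7, 1.0 - 1e-7)  # (N, 1, H, W)
        out = x * att
        self._cache = (x, att)
        return att[:, 0], out

    def backward(self, dout):
        x, att = self._cache
        n, c, h, w = x.shape
        dx = dout * att
        datt = (dout * x).sum(axis=1, keepdims=True)
        dz = datt * att * (1.0 - att)
        dcat = self.conv.backward(dz)
        dmx, dav = dcat[:, 0], dcat[:, 1]
        dx = dx + dav[:, None, :, :] / c
        scatter = np.zeros_like(dx)
        np.put_along_axis(scatter, self._argmax[:, None, :, :], dmx[:, None, :, :], axis=1)
        return (dx + scatter).astype(np.float32, copy=False)


class CBAM(Module):
    """Sequential channel-then-spatial attention refinement."""

    def __init__(self, channels, reduction, spatial_kernel, name="cbam"):
        super().__init__(name)
        self.cam = ChannelAttention(channels, reduction, name=f"{name}.cam")
        self.sam = SpatialAttention(spatial_kernel, name=f"{name}.sam")

    def children(self):
        return iter([self.cam, self.sam])

    def init_weights(self, rng):
        self.cam.init_weights(rng)
        self.sam.init_weights(rng)

    def forward(self, x, train=False):
        return self.sam.forward(self.cam.forward(x, train), train)

    def backward(self, dout):
        return self.cam.backward(self.sam.backward(dout))


class CellSage(Module):
    """Full classifier; ``variant`` controls the ablations."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__("cellsage")
        config.validate()
        self.config = config
        self.seed = seed
        cat = config.mscfe_out_channels
        if config.variant == "no_mscfe":
            # single 3x3 conv producing the same channel count as the three
            # concatenated branches, so downstream shapes are unchanged
            self.mscfe = Sequential(
                [Conv2d(config.input_channels, cat, 3, stride=config.mscfe_stride,
                        name="mscfe.conv3x3"), ReLU()],
                name="mscfe")
        else:
            self.mscfe = MSCFE(config)
        self.blocks: list[DWBlock] = []
        cin = cat
        for si, width in enumerate(config.stage_widths):
            for bi in range(config.blocks_per_stage):
                stride = 2 if bi == 0 else 1
                self.blocks.append(DWBlock(cin, width, stride, config.dropout_rate,
                                           name=f"stage{si}.block{bi}"))
                cin = width
        self.stack = Sequential(self.blocks, name="stack")
        self.cbam = (None if config.variant == "no_cbam"
                     else CBAM(cin, config.cbam_reduction_ratio,
                               config.spatial_kernel))
        self.pool = GlobalAvgPool()
        self.head_drop = Dropout(config.dropout_rate, name="head.drop")
        self.head = Linear(cin, 1, name="head.fc")
        self._init(seed)

    # -- construction --------------------------------------------------------
    def _init(self, seed: int) -> None:
        """He-normal conv/linear weights, zero biases, identity batch norm."""
        rng = np.random.default_rng(seed)
        for m in self.modules():
            if isinstance(m, (Conv2d, Linear)):
                m.init_weights(rng)

    def children(self):
        yield self.mscfe
        yield self.stack
        if self.cbam is not None:
            yield self.cbam
        yield self.head_drop
        yield self.head

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = rng

    # -- forward / backward --------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False,
                       capture: dict | None = None) -> np.ndarray:
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != cfg.input_channels:
            raise ValueError(f"expected (N, {cfg.input_channels}, H, W) input, "
                             f"got shape {x.shape}")
        if x.shape[2] != cfg.input_size or x.shape[3] != cfg.input_size:
            raise ValueError(f"expected {cfg.input_size}x{cfg.input_size} input, "
                             f"got {x.shape[2]}x{x.shape[3]}")
        h = self.mscfe.forward(x.astype(np.float32, copy=False), train)
        h = self.stack.forward(h, train)
        if self.cbam is not None:
            h = self.cbam.forward(h, train)
        if capture is not None:
            capture["features"] = h
        v = self.pool.forward(h, train)
        v = self.head_drop.forward(v, train)
        return self.head.forward(v, train)[:, 0]

    def forward(self, x, train=False):
        """Probability that each sample is malignant, in (0, 1)."""
        return sigmoid(self.forward_logits(x, train))

    def backward_from_logits(self, dlogits: np.ndarray,
                             capture: dict | None = None) -> np.ndarray:
        d = self.head.backward(dlogits[:, None])
        d = self.head_drop.backward(d)
        d = self.pool.backward(d)
        if capture is not None:
            capture["features_grad"] = d
        if self.cbam is not None:
            d = self.cbam.backward(d)
        d = self.stack.backward(d)
        return self.mscfe.backward(d)

    # -- weights i/o ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        sd = {name: v.copy() for name, v, _, _ in self.all_parameters()}
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                sd[f"{m.name}.running_mean"] = m.running_mean.copy()
                sd[f"{m.name}.running_var"] = m.running_var.copy()
        return sd

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        for name, v, mod, key in self.all_parameters():
            if name not in sd:
                raise KeyError(f"missing weight {name!r} in state dict")
            if sd[name].shape != v.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            mod.params[key] = sd[name].astype(np.float32).copy()
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = sd[f"{m.name}.running_mean"].astype(np.float32).copy()
                m.running_var = sd[f"{m.name}.running_var"].astype(np.float32).copy()

    def save_checkpoint(self, path: str | Path) -> None:
        """Self-describing archive: config JSON + every weight array."""
        payload = dict(self.state_dict())
        payload["__config__"] = np.frombuffer(
            json.dumps({"config": self.config.to_dict(), "seed": self.seed}).encode(),
            dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **payload)


def load_checkpoint(path: str | Path) -> CellSage:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__config__"]).decode())
        sd = {k: z[k] for k in z.files if k != "__config__"}
    model = CellSage(ModelConfig.from_dict(meta["config"]), seed=meta.get("seed", 0))
    model.load_state_dict(sd)
    return model


# -- spec-level operation surface -------------------------------------------

def build_model(config: ModelConfig, seed: int = 0) -> CellSage:
    """Build and He-initialize the network; (config, seed) fixes all weights."""
    return CellSage(config, seed=seed)


def build_variant(config: ModelConfig, variant: str, seed: int = 0) -> CellSage:
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return CellSage(config.with_variant(variant), seed=seed)


def mscfe_forward(x: FeatureMap, model: CellSage) -> FeatureMap:
    if x.role != "input_x":
        raise ValueError(f"expected role 'input_x', got {x.role!r}")
    if x.channels != model.config.input_channels:
        raise ValueError(f"channel mismatch: expected {model.config.input_channels}, "
                         f"got {x.channels}")
    return FeatureMap(model.mscfe.forward(x.values.astype(np.float32)), "f_mscfe")


def dwb_forward(f: FeatureMap, model: CellSage) -> FeatureMap:
    if f.role != "f_mscfe":
        raise ValueError(f"expected role 'f_mscfe', got {f.role!r}")
    if f.channels != model.config.mscfe_out_channels:
        raise ValueError("channel mismatch entering depthwise-separable stack")
    return FeatureMap(model.stack.forward(f.values.astype(np.float32)), "f_dwb")


def channel_attention(f: FeatureMap, model: CellSage):
    if f.role != "f_dwb":
        raise ValueError(f"expected role 'f_dwb', got {f.role!r}")
    if model.cbam is None:
        raise ConfigError("variant 'no_cbam' has no attention stage")
    att, out = model.cbam.cam.attend(f.values.astype(np.float32))
    return AttentionMaps(channel_map=att), FeatureMap(out, "f_prime")


def spatial_attention(f_prime: FeatureMap, model: CellSage):
    if f_prime.role != "f_prime":
        raise ValueError(f"expected role 'f_prime', got {f_prime.role!r}")
    if model.cbam is None:
        raise ConfigError("variant 'no_cbam' has no attention stage")
    att, out = model.cbam.sam.attend(f_prime.values.astype(np.float32))
    return AttentionMaps(spatial_map=att), FeatureMap(out, "f_double_prime")


def forward(x: np.ndarray, model: CellSage) -> np.ndarray:
    """Evaluation-mode malignancy probabilities for a preprocessed batch."""
    return model.forward(x, train=False)
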