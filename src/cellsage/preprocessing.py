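"""Image preparation: reference-stain color mapping, augmentation, and the
rescale/standardize step with the fixed ImageNet channel statistics.

The stain normalizer is a Reinhard-style appearance transfer: the image is
moved to CIELAB, each channel is affinely mapped so its mean and standard
deviation match a reference profile, and the result is mapped back to RGB.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import color as skcolor
from skimage.transform import AffineTransform, resize, warp

# fixed standardization constants (channel order R, G, B)
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float64)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float64)

_EPS_STD = 1e-6


class ImageFormatError(ValueError):
    pass


def _as_rgb_float(image: np.ndarray) -> np.ndarray:
    """Validate and return an H x W x 3 float64 array in [0, 255]."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"expected an H x W x 3 RGB image, got shape {arr.shape}")
    if arr.size == 0:
        raise ImageFormatError("empty image")
    return arr.astype(np.float64)


@dataclass
class ReferenceStainProfile:
    """Per-channel mean/std of the reference appearance in CIELAB."""

    channel_means: np.ndarray
    channel_stds: np.ndarray
    space_tag: str = "cielab"

    def __post_init__(self):
        self.channel_means = np.asarray(self.channel_means, dtype=np.float64)
        self.channel_stds = np.asarray(self.channel_stds, dtype=np.float64)
        if self.channel_means.shape != (3,) or self.channel_stds.shape != (3,):
            raise ValueError("profile means/stds must be 3-vectors")
        if not (np.all(np.isfinite(self.channel_means))
                and np.all(np.isfinite(self.channel_stds))):
            raise ValueError("profile values must be finite")
        if np.any(self.channel_stds <= 0):
            raise ValueError("profile stds must be strictly positive")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "space_tag": self.space_tag,
            "channel_means": self.channel_means.tolist(),
            "channel_stds": self.channel_stds.tolist(),
        }, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceStainProfile":
        d = json.loads(Path(path).read_text())
        return cls(d["channel_means"], d["channel_stds"], d.get("space_tag", "cielab"))


def _to_lab(rgb255: np.ndarray) -> np.ndarray:
    return skcolor.rgb2lab(np.clip(rgb255 / 255.0, 0.0, 1.0))


def _from_lab(lab: np.ndarray) -> np.ndarray:
    return np.clip(skcolor.lab2rgb(lab), 0.0, 1.0) * 255.0


def extract_stain_profile(image: np.ndarray) -> ReferenceStainProfile:
    """Measure the CIELAB channel statistics of a reference image."""
    lab = _to_lab(_as_rgb_float(image))
    means = lab.reshape(-1, 3).mean(axis=0)
    stds = lab.reshape(-1, 3).std(axis=0)
    return ReferenceStainProfile(means, np.maximum(stds, _EPS_STD))


def stain_normalize(image: np.ndarray, profile: ReferenceStainProfile) -> np.ndarray:
    """Map the image's color distribution onto the reference stain.

    Returns a float RGB image in [0, 255]. Zero-variance channels collapse
    onto the reference mean rather than dividing by zero.
    """
    rgb = _as_rgb_float(image)
    lab = _to_lab(rgb)
    flat = lab.reshape(-1, 3)
    means = flat.mean(axis=0)
    stds = flat.std(axis=0)
    scale = np.where(stds > _EPS_STD, profile.channel_stds / np.maximum(stds, _EPS_STD), 0.0)
    mapped = (lab - means) * scale + profile.channel_means
    return _from_lab(mapped)


def rescale_standardize(image: np.ndarray) -> np.ndarray:
    """[0, 255] H x W x 3 -> standardized 3 x H x W tensor."""
    rgb = _as_rgb_float(image)
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError(f"pixel values outside [0, 255]: "
                         f"min={rgb.min():.3g}, max={rgb.max():.3g}")
    scaled = rgb / 255.0
    standardized = (scaled - IMAGENET_MEAN) / IMAGENET_STD
    return standardized.transpose(2, 0, 1).astype(np.float32)


@dataclass
class AugmentationPolicy:
    """Training-time augmentation ranges."""

    max_rotation: float = 30.0          # degrees, sampled in [-max, +max]
    hflip: bool = True
    vflip: bool = True
    zoom_range: tuple[float, float] = (0.8, 1.2)
    max_shift: float = 20.0             # pixels, each axis
    brightness: float = 0.10            # relative
    contrast: float = 0.10
    saturation: float = 0.10
    hue: float = 0.02

    def __post_init__(self):
        if not 0.0 <= self.max_rotation <= 180.0:
            raise ValueError("max_rotation must be in [0, 180]")
        lo, hi = self.zoom_range
        if lo > hi or (lo < hi and not lo <= 1.0 <= hi) or (lo == hi and lo != 1.0 and lo <= 0):
            raise ValueError("zoom_range must contain 1 or be degenerate")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (self.max_rotation == 0 and not self.hflip and not self.vflip
                and self.zoom_range == (1.0, 1.0) and self.max_shift == 0
                and self.brightness == 0 and self.contrast == 0
                and self.saturation == 0 and self.hue == 0)


IDENTITY_POLICY = AugmentationPolicy(max_rotation=0.0, hflip=False, vflip=False,
                                     zoom_range=(1.0, 1.0), max_shift=0.0,
                                     brightness=0.0, contrast=0.0,
                                     saturation=0.0, hue=0.0)


def sample_augmentation(policy: AugmentationPolicy, rng: np.random.Generator) -> dict:
    """Draw one set of augmentation parameters from the policy."""
    lo, hi = policy.zoom_range
    return {
        "angle": float(rng.uniform(-policy.max_rotation, policy.max_rotation)),
        "hflip": bool(policy.hflip and rng.random() < 0.5),
        "vflip": bool(policy.vflip and rng.random() < 0.5),
        "zoom": float(rng.uniform(lo, hi)),
        "shift": (float(rng.uniform(-policy.max_shift, policy.max_shift)),
                  float(rng.uniform(-policy.max_shift, policy.max_shift))),
        "brightness": float(rng.uniform(-policy.brightness, policy.brightness)),
        "contrast": float(rng.uniform(-policy.contrast, policy.contrast)),
        "saturation": float(rng.uniform(-policy.saturation, policy.saturation)),
        "hue": float(rng.uniform(-policy.hue, policy.hue)),
    }


def _apply_geometry(rgb: np.ndarray, p: dict) -> np.ndarray:
    if p["hflip"]:
        rgb = rgb[:, ::-1]
    if p["vflip"]:
        rgb = rgb[::-1, :]
    if p["angle"] == 0 and p["zoom"] == 1.0 and p["shift"] == (0.0, 0.0):
        return np.ascontiguousarray(rgb)
    h, w = rgb.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t = (AffineTransform(translation=-center)
         + AffineTransform(rotation=np.deg2rad(p["angle"]), scale=p["zoom"])
         + AffineTransform(translation=center + np.array(p["shift"])))
    # warp uses the inverse map; bilinear interpolation, reflected borders
    return warp(rgb / 255.0, t.inverse, order=1, mode="reflect",
                preserve_range=True) * 255.0


def _apply_color(rgb: np.ndarray, p: dict) -> np.ndarray:
    out = rgb * (1.0 + p["brightness"])
    mean = out.mean(axis=(0, 1), keepdims=True)
    out = mean + (out - mean) * (1.0 + p["contrast"])
    out = np.clip(out, 0.0, 255.0)
    if p["saturation"] or p["hue"]:
        hsv = skcolor.rgb2hsv(out / 255.0)
        hsv[..., 0] = np.mod(hsv[..., 0] + p["hue"], 1.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + p["saturation"]), 0.0, 1.0)
        out = skcolor.hsv2rgb(hsv) * 255.0
    return np.clip(out, 0.0, 255.0)


def augment(image: np.ndarray, policy: AugmentationPolicy, draw_seed: int) -> np.ndarray:
    """Seeded geometric + color augmentation on raw-range RGB pixels."""
    rgb = _as_rgb_float(image)
    if policy.is_identity:
        return rgb
    p = sample_augmentation(policy, np.random.default_rng(draw_seed))
    return _apply_color(_apply_geometry(rgb, p), p)


def resize_patch(image: np.ndarray, target_size: int) -> np.ndarray:
    rgb = _as_rgb_float(image)
    if rgb.shape[0] == target_size and rgb.shape[1] == target_size:
        return rgb
    out = resize(rgb / 255.0, (target_size, target_size), order=1,
                 mode="reflect", anti_aliasing=False, preserve_range=True)
    return np.clip(out * 255.0, 0.0, 255.0)


def preprocess_image(image: np.ndarray,
                     profile: ReferenceStainProfile,
                     target_size: int = 224,
                     train_mode: bool = False,
                     draw_seed: int = 0,
                     policy: AugmentationPolicy | None = None) -> np.ndarray:
    """stain_normalize -> (augment if training) -> resize -> standardize."""
    out = stain_normalize(image, profile)
    if train_mode:
        out = augment(out, policy if policy is not None else AugmentationPolicy(),
                      draw_seed)
    out = resize_patch(out, target_size)
    return rescale_standardize(out)
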