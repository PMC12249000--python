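"""Gradient-weighted class activation maps and heat-map overlays."""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .config import ConfigError


def grad_cam(model, image: np.ndarray, upsample_to: int | None = None) -> np.ndarray:
    """Saliency map for the malignant logit in [0, 1].

    ``model`` must expose ``forward_logits(x, train, capture)`` and
    ``backward_from_logits(dlogits, capture)`` where ``capture['features']``
    receives the target layer's activations (the final attention-refined
    feature map) and ``capture['features_grad']`` its gradient. Gradients are
    spatially averaged into per-channel weights, the weighted activation sum
    is rectified, min-max normalized (all-zero map when the range is
    degenerate), and bilinearly upsampled.
    """
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    capture: dict = {}
    model.forward_logits(x, train=False, capture=capture)
    for m in model.modules():
        m.zero_grad()
    model.backward_from_logits(np.ones(x.shape[0], dtype=np.float32), capture)
    feats = capture["features"]
    grads = capture["features_grad"]
    if feats.ndim != 4 or feats.shape[2] < 1 or feats.shape[3] < 1:
        raise ConfigError("target layer has no spatial extent")
    weights = grads.mean(axis=(2, 3))                      # (N, C)
    cam = np.maximum((weights[:, :, None, None] * feats).sum(axis=1), 0.0)
    out = np.zeros_like(cam)
    for i in range(cam.shape[0]):
        lo, hi = cam[i].min(), cam[i].max()
        if hi > lo:
            out[i] = (cam[i] - lo) / (hi - lo)
    if upsample_to is not None and out.shape[1:] != (upsample_to, upsample_to):
        out = np.stack([
            np.clip(resize(m, (upsample_to, upsample_to), order=1,
                           mode="edge", anti_aliasing=False), 0.0, 1.0)
            for m in out])
    return out[0] if image.ndim == 3 else out


def render_overlay(cam: np.ndarray, image_rgb: np.ndarray,
                   alpha: float = 0.45) -> np.ndarray:
    """Blend a blue-to-red heat map over an RGB image (uint8 output)."""
    cam = np.asarray(cam, dtype=np.float64)
    img = np.asarray(image_rgb, dtype=np.float64)
    if img.max() <= 1.0:
        img = img * 255.0
    if cam.shape != img.shape[:2]:
        cam = np.clip(resize(cam, img.shape[:2], order=1, mode="edge",
                             anti_aliasing=False), 0.0, 1.0)
    heat = colormaps["jet"](cam)[..., :3] * 255.0  # blue = low, red = high
    blended = (1.0 - alpha) * img + alpha * heat
    return np.clip(blended, 0.0, 255.0).astype(np.uint8)
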