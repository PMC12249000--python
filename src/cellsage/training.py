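"""Training recipe: Adam, cosine annealing with warm restarts, weighted
binary cross-entropy on logits, early stopping, and patient-leakage guards."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data import DatasetIndex, check_no_leakage
from .metrics import FoldEntry, compute_metrics
from .model import CellSage
from .nn import Conv2d, Linear, sigmoid
from .preprocessing import AugmentationPolicy, ReferenceStainProfile, preprocess_image


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    scheduler_t0: int = 10       # warm-restart cycle length (epochs)
    scheduler_tmult: int = 2
    eta_min: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("Adam betas must be in [0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def cosine_warm_restart_lr(epoch: int, config: TrainConfig) -> float:
    """Learning rate at a 0-based epoch; epoch 0 returns the initial rate."""
    t_i = config.scheduler_t0
    t_cur = epoch
    while t_cur >= t_i:
        t_cur -= t_i
        t_i *= config.scheduler_tmult
    return config.eta_min + 0.5 * (config.learning_rate - config.eta_min) \
        * (1.0 + math.cos(math.pi * t_cur / t_i))


class Adam:
    def __init__(self, model: CellSage, config: TrainConfig):
        self.model = model
        self.b1, self.b2 = config.beta1, config.beta2
        self.eps = 1e-8
        self.t = 0
        self.m = {n: np.zeros_like(v) for n, v, _, _ in model.all_parameters()}
        self.v = {n: np.zeros_like(v) for n, v, _, _ in model.all_parameters()}

    def zero_grad(self):
        for mod in self.model.modules():
            mod.zero_grad()

    def step(self, lr: float):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for name, value, mod, key in self.model.all_parameters():
            g = mod.grads[key]
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / bc1
            vhat = self.v[name] / bc2
            mod.params[key] = (value - lr * mhat / (np.sqrt(vhat) + self.eps)
                               ).astype(np.float32)


@dataclass
class ArrayDataset:
    """Preprocessed tensors with labels and owning patients."""

    x: np.ndarray          # (N, 3, S, S) float32
    y: np.ndarray          # (N,) float32 in {0, 1}
    patients: list[str]

    def __post_init__(self):
        if len(self.x) != len(self.y) or len(self.y) != len(self.patients):
            raise ValueError("inconsistent dataset lengths")

    def __len__(self):
        return len(self.y)

    @property
    def patient_set(self) -> set[str]:
        return set(self.patients)

    @classmethod
    def from_index(cls, index: DatasetIndex, profile: ReferenceStainProfile,
                   input_size: int, train_mode: bool = False, seed: int = 0,
                   policy: AugmentationPolicy | None = None) -> "ArrayDataset":
        xs, ys, ps = [], [], []
        for i, rec in enumerate(index.records):
            img = np.asarray(Image.open(rec.image_path).convert("RGB"))
            xs.append(preprocess_image(img, profile, input_size,
                                       train_mode=train_mode,
                                       draw_seed=seed * 1_000_003 + i,
                                       policy=policy))
            ys.append(1.0 if rec.class_label == "malignant" else 0.0)
            ps.append(rec.patient_id)
        return cls(np.stack(xs), np.asarray(ys, dtype=np.float32), ps)


def bce_with_logits(logits: np.ndarray, y: np.ndarray,
                    weights: np.ndarray | None = None):
    """Stable weighted binary cross-entropy; returns (loss, dloss/dlogits)."""
    z, y = logits.astype(np.float64), y.astype(np.float64)
    per = np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
    w = np.ones_like(per) if weights is None else weights.astype(np.float64)
    n = len(z)
    loss = float((w * per).sum() / n)
    dz = w * (sigmoid(z) - y) / n
    return loss, dz.astype(np.float32)


def predict_proba(model: CellSage, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = [model.forward(x[i:i + batch_size], train=False)
           for i in range(0, len(x), batch_size)]
    return np.concatenate(out)


class LeakageError(RuntimeError):
    pass


def _sample_weights(y: np.ndarray, class_weights: dict[str, float] | None):
    if class_weights is None:
        return None
    w = np.where(y > 0.5, class_weights["malignant"], class_weights["benign"])
    return w.astype(np.float64)


def train(model: CellSage, train_ds: ArrayDataset, val_ds: ArrayDataset,
          config: TrainConfig, class_weights: dict[str, float] | None = None):
    """Optimize; returns (model restored to best-validation weights, epoch log).

    The log is a DataFrame with one row per epoch: epoch, lr, train_loss,
    val_loss, val_accuracy, val_f1, val_auc.
    """
    overlap = train_ds.patient_set & val_ds.patient_set
    if overlap:
        raise LeakageError(f"patients in both train and val: {sorted(overlap)}")
    rng = np.random.default_rng(config.seed)
    model.set_dropout_rng(np.random.default_rng(
        np.random.SeedSequence([config.seed, 13])))
    opt = Adam(model, config)
    best_loss = math.inf
    best_state = model.state_dict()
    best_epoch = -1
    bad_epochs = 0
    rows = []
    n = len(train_ds)
    for epoch in range(config.max_epochs):
        lr = cosine_warm_restart_lr(epoch, config)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = train_ds.x[idx], train_ds.y[idx]
            opt.zero_grad()
            logits = model.forward_logits(xb, train=True)
            loss, dz = bce_with_logits(logits, yb, _sample_weights(yb, class_weights))
            model.backward_from_logits(dz)
            opt.step(lr)
            losses.append(loss)
        val_logits = np.concatenate(
            [model.forward_logits(val_ds.x[i:i + config.batch_size], train=False)
             for i in range(0, len(val_ds), config.batch_size)])
        val_loss, _ = bce_with_logits(val_logits, val_ds.y,
                                      _sample_weights(val_ds.y, class_weights))
        entry = compute_metrics(val_ds.y, sigmoid(val_logits))
        rows.append({"epoch": epoch, "lr": lr,
                     "train_loss": float(np.mean(losses)), "val_loss": val_loss,
                     "val_accuracy": entry.accuracy, "val_f1": entry.f1,
                     "val_auc": entry.auc})
        if val_loss < best_loss - 1e-12:
            best_loss, best_epoch, bad_epochs = val_loss, epoch, 0
            best_state = model.state_dict()
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stop_patience:
                break
    model.load_state_dict(best_state)
    log = pd.DataFrame(rows)
    log.attrs["best_epoch"] = best_epoch
    return model, log


def evaluate(model: CellSage, test_ds: ArrayDataset, threshold: float = 0.5,
             train_patients: set[str] | None = None) -> FoldEntry:
    """Held-out metrics; refuses any train/test patient overlap."""
    if train_patients is not None:
        overlap = set(train_patients) & test_ds.patient_set
        if overlap:
            raise LeakageError(f"patients in both train and test: {sorted(overlap)}")
    scores = predict_proba(model, test_ds.x)
    return compute_metrics(test_ds.y, scores, threshold)
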