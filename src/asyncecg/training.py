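"""Training: random lead masking, augmentation, patient-level splits, Adam.

The central training trick is the per-sample, per-step random lead mask:
each of the 12 lead channels is dropped from the attention matrices with
probability ``mask_prob`` (redrawn if all 12 would vanish), so one trained
model serves any lead subset at inference without retraining.

Augmentations (additive Gaussian noise, time scaling with resampling back
to the input length, zeroing of a random contiguous window) are applied
independently per segment.  The loss is binary cross-entropy on the sigmoid
output; optimization is Adam (batch 32, learning rate 0.001 by default)
with L2 weight decay on convolution/dense weight matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evaluation import roc_pr
from .leads import LEAD_NAMES
from .nn.layers import DTYPE, BatchNorm1d, sigmoid
from .nn.network import AsyncEcgClassifier


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    max_epochs: int = 20
    patience: int = 10
    mask_prob: float = 0.5
    noise_sd: float = 0.05
    noise_prob: float = 0.3
    time_scale_range: tuple[float, float] = (0.9, 1.1)
    time_scale_prob: float = 0.3
    signal_mask_max_frac: float = 0.1
    signal_mask_prob: float = 0.3
    stop_auroc: Optional[float] = None  # stop early once val AUROC reaches this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.mask_prob < 1.0:
            raise ValueError("mask_prob must be in [0, 1)")


@dataclass
class SplitSpec:
    """80/20 train+val vs test, then 85/15 train vs val, grouped by patient."""

    trainval_fraction: float = 0.80
    train_fraction_within_trainval: float = 0.85

    def __post_init__(self) -> None:
        for f in (self.trainval_fraction, self.train_fraction_within_trainval):
            if not 0.0 < f < 1.0:
                raise ValueError("split fractions must be in (0, 1)")


def sample_lead_mask(
    rng: np.random.Generator, mask_prob: float, n_leads: int = 12
) -> np.ndarray:
    """Draw an availability mask; each lead masked independently.

    Redrawn until at least one lead stays available, so every availability
    pattern with >= 1 lead has positive probability and the all-masked
    pattern never occurs.
    """
    while True:
        available = rng.random(n_leads) >= mask_prob
        if available.any():
            return available


def mask_signal_window(
    segment: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero exactly floor(fraction * len) consecutive samples."""
    out = segment.copy()
    width = int(fraction * len(segment))
    if width > 0:
        start = int(rng.integers(0, len(segment) - width + 1))
        out[start : start + width] = 0.0
    return out


def time_scale(
    segment: np.ndarray, factor: float
) -> np.ndarray:
    """Stretch time by ``factor`` and resample back to the original length."""
    n = len(segment)
    m = max(2, int(round(n * factor)))
    stretched = np.interp(
        np.linspace(0.0, n - 1.0, m), np.arange(n), segment
    )
    return np.interp(
        np.linspace(0.0, m - 1.0, n), np.arange(m), stretched
    ).astype(segment.dtype)


def augment(
    segment: np.ndarray, rng: np.random.Generator, config: TrainConfig
) -> np.ndarray:
    """Apply each augmentation with its own independent probability."""
    out = np.asarray(segment, dtype=DTYPE)
    if config.time_scale_prob > 0 and rng.random() < config.time_scale_prob:
        out = time_scale(out, rng.uniform(*config.time_scale_range))
    if config.signal_mask_prob > 0 and rng.random() < config.signal_mask_prob:
        frac = rng.uniform(0.0, config.signal_mask_max_frac)
        out = mask_signal_window(out, frac, rng)
    if config.noise_prob > 0 and rng.random() < config.noise_prob:
        out = out + rng.normal(0.0, config.noise_sd, out.shape).astype(DTYPE)
    return out


def split_by_patient(
    records: Sequence, spec: SplitSpec, rng: np.random.Generator
) -> tuple[list, list, list]:
    """Partition records into (train, validation, test) disjoint by patient."""
    if not records:
        raise ValueError("cannot split an empty record list")
    subjects = sorted({r.subject_id for r in records})
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    n_trainval = int(round(spec.trainval_fraction * len(order)))
    trainval, test = set(order[:n_trainval]), set(order[n_trainval:])
    tv_order = [s for s in order if s in trainval]
    n_train = int(round(spec.train_fraction_within_trainval * len(tv_order)))
    train_subj = set(tv_order[:n_train])
    train = [r for r in records if r.subject_id in train_subj]
    val = [r for r in records if r.subject_id in trainval - train_subj]
    test_recs = [r for r in records if r.subject_id in test]
    return train, val, test_recs


class Adam:
    """Adam with L2 weight decay applied to weight matrices only.

    Batch-norm scale/shift and bias vectors are excluded from decay, the
    usual practice for normalized networks.
    """

    def __init__(
        self,
        model: AsyncEcgClassifier,
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.model = model
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.model.layers):
            decay_ok = not isinstance(layer, BatchNorm1d)
            for key, p in layer.params.items():
                g = layer.grads[key]
                if decay_ok and self.weight_decay and key.startswith("w"):
                    g = g + self.weight_decay * p
                slot = (i, key)
                if slot not in self.m:
                    self.m[slot] = np.zeros_like(p)
                    self.v[slot] = np.zeros_like(p)
                self.m[slot] = b1 * self.m[slot] + (1 - b1) * g
                self.v[slot] = b2 * self.v[slot] + (1 - b2) * g * g
                mhat = self.m[slot] / (1 - b1**self.t)
                vhat = self.v[slot] / (1 - b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
        self.model.zero_grads()


def bce_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Binary cross-entropy, clipped for numerical safety."""
    p = np.clip(np.asarray(probabilities, dtype=np.float64), 1e-12, 1 - 1e-12)
    y = np.asarray(labels, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def training_step(
    model: AsyncEcgClassifier,
    x_batch: np.ndarray,
    y_batch: np.ndarray,
    masks: np.ndarray,
    optimizer: Adam,
) -> float:
    """One gradient step; returns the pre-update batch BCE loss."""
    logits = model.forward_logits(x_batch, masks, train=True)
    probs = sigmoid(logits)
    loss = bce_loss(probs, y_batch)
    dlogits = (probs - y_batch).astype(DTYPE) / len(y_batch)
    model.backward_from_logits(dlogits)
    optimizer.step()
    return loss


def evaluate_auroc(
    model: AsyncEcgClassifier,
    x: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    batch_size: int = 64,
) -> tuple[float, np.ndarray]:
    scores = predict_scores(model, x, mask, batch_size)
    return roc_pr(scores, y).auroc, scores


def predict_scores(
    model: AsyncEcgClassifier,
    x: np.ndarray,
    mask: np.ndarray,
    batch_size: int = 64,
) -> np.ndarray:
    out = []
    for i in range(0, len(x), batch_size):
        out.append(model.predict_proba(x[i : i + batch_size], mask))
    return np.concatenate(out)


def train(
    model: AsyncEcgClassifier,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> list[dict]:
    """Fit the model; returns per-epoch history.

    A fresh lead mask is drawn per sample per step; augmentations apply to
    the available leads only.  The best parameters by validation AUROC
    (computed with all leads available) are restored on exit.
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(
        model, lr=config.learning_rate, weight_decay=config.weight_decay
    )
    n_leads = model.config.n_leads
    full_mask = np.ones(n_leads, dtype=bool)
    history: list[dict] = []
    best_auroc = -np.inf
    best_state = None
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx].copy()
            masks = np.stack(
                [sample_lead_mask(rng, config.mask_prob, n_leads) for _ in idx]
            )
            for r in range(len(idx)):
                for lead in np.flatnonzero(masks[r]):
                    xb[r, lead] = augment(xb[r, lead], rng, config)
            losses.append(
                training_step(model, xb, y_train[idx], masks, optimizer)
            )
        val_scores = predict_scores(model, x_val, full_mask)
        val_loss = bce_loss(val_scores, y_val)
        if len(np.unique(y_val)) > 1:
            val_auroc = roc_pr(val_scores, y_val).auroc
        else:
            val_auroc = float("nan")
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_auroc": val_auroc,
            }
        )
        if np.isnan(val_auroc) or val_auroc > best_auroc:
            best_auroc = val_auroc
            best_state = {
                k: v.copy() for k, v in model.state_arrays().items()
            }
            since_best = 0
        else:
            since_best += 1
        if since_best >= config.patience:
            break
        if config.stop_auroc is not None and val_auroc >= config.stop_auroc:
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return history
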