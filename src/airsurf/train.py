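"""Huber-loss optimization with Adam and exponential learning-rate decay.

The schedule is lr(step) = initial_lr * decay_rate**(step / decay_steps),
continuous by default (``staircase=True`` floors the exponent). Training is
seeded and deterministic on one device: mini-batch order, dropout draws,
and initialization all derive from explicit seeds.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TrainConfig
from .model import PM25SequenceModel
from .features import SequenceDataset
from .nn import Tensor

__all__ = ["huber_loss", "lr_schedule", "Adam", "train", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; carries the offending step for diagnosis."""


def huber_loss(y_true: np.ndarray, y_pred, delta: float = 1.0):
    """Mean Huber loss: 0.5*r^2 for |r| <= delta, delta*(|r| - delta/2) beyond.

    Accepts a ``Tensor`` prediction (for training) or plain arrays; returns
    the same kind. The quadratic/linear switch is made on the forward
    values, so the gradient is exact and continuous at |r| = delta.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if isinstance(y_pred, Tensor):
        r = y_pred - np.asarray(y_true, dtype=float)
        a = np.abs(r.data)
        quad = (a <= delta).astype(float)
        absr = r * np.sign(r.data)
        per = (r * r * 0.5) * quad + (absr * delta - 0.5 * delta ** 2) * (1.0 - quad)
        return per.mean()
    r = np.asarray(y_pred, dtype=float) - np.asarray(y_true, dtype=float)
    a = np.abs(r)
    per = np.where(a <= delta, 0.5 * r ** 2, delta * (a - 0.5 * delta))
    return float(per.mean())


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Exponential decay: decay_rate every decay_steps steps."""
    if step < 0:
        raise ValueError("step must be >= 0")
    exponent = step / config.decay_steps
    if config.staircase:
        exponent = np.floor(exponent)
    return config.initial_lr * config.decay_rate ** exponent


class Adam:
    """Adaptive moment estimation over a parameter list."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    weights: list[np.ndarray]          # best-validation weights
    history: pd.DataFrame              # per-epoch losses and lr
    best_epoch: int
    best_val_loss: float
    manifest: dict = field(default_factory=dict)


def _rmse(a, b) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def _clip_global_norm(params: list[Tensor], max_norm: float) -> None:
    """Rescale all gradients so their joint L2 norm is at most max_norm —
    the usual guard against exploding recurrent gradients."""
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def train(model: PM25SequenceModel, train_ds: SequenceDataset,
          val_ds: SequenceDataset | None, config: TrainConfig) -> TrainResult:
    """Seeded mini-batch training; retains the best-validation weights.

    Without a validation set the training loss drives checkpointing and
    early stopping.
    """
    config.validate()
    if len(train_ds) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters())
    best_weights = model.get_weights()
    best_val = np.inf
    best_epoch = -1
    rows = []
    step = 0
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_ds))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            pred, _ = model.forward(train_ds.X[idx], train_ds.mask[idx],
                                    training=True)
            loss = huber_loss(train_ds.y_scaled[idx], pred, config.huber_delta)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {step}")
            loss.backward()
            if config.clip_norm > 0:
                _clip_global_norm(model.parameters(), config.clip_norm)
            opt.step(lr_schedule(step, config))
            step += 1
            epoch_losses.append(float(loss.data))
        train_loss = float(np.mean(epoch_losses))

        if val_ds is not None and len(val_ds):
            val_pred = model.predict(val_ds.X, val_ds.mask)
            val_loss = huber_loss(val_ds.y_scaled, val_pred, config.huber_delta)
            val_rmse = _rmse(val_ds.y_scaled, val_pred)
        else:
            val_loss, val_rmse = train_loss, np.nan
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss, "val_rmse_scaled": val_rmse,
                     "lr": lr_schedule(step, config)})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if config.early_stopping and since_best >= config.patience:
                break

    model.set_weights(best_weights)
    history = pd.DataFrame(rows)
    manifest = {"train_config": vars(config).copy(), "n_train": len(train_ds),
                "n_val": 0 if val_ds is None else len(val_ds),
                "steps": step, "best_epoch": best_epoch}
    return TrainResult(best_weights, history, best_epoch, best_val, manifest)
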