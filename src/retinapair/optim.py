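"""Optimizers and training-loop scheduling utilities.

AdamW follows the decoupled weight-decay formulation; the plateau scheduler
and early stopper mirror the downstream-adaptation protocol (reduce-on-
plateau learning rate, stop after five non-improving validation epochs).
"""

from __future__ import annotations

import math

import numpy as np

from .nn import Parameter


class AdamW:
    """Adam with decoupled weight decay.

    ``decay_mask`` lets callers exclude parameters (biases, temperature)
    from weight decay, matching common contrastive-training practice.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.1,
        decay_mask: list[bool] | None = None,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.decay_mask = list(decay_mask) if decay_mask is not None else [True] * len(self.params)
        if len(self.decay_mask) != len(self.params):
            raise ValueError("decay_mask length must match params")
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            if self.decay_mask[i] and self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_warmup_lr(step: int, total_steps: int, base_lr: float, warmup_steps: int = 0) -> float:
    """Linear warmup followed by cosine decay to zero."""
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    span = max(1, total_steps - warmup_steps)
    frac = min(1.0, (step - warmup_steps) / span)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * frac))


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` stagnant epochs."""

    def __init__(self, optimizer: AdamW, factor: float = 0.5, patience: int = 2, min_lr: float = 1e-8):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = math.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> None:
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.min_lr, self.optimizer.lr * self.factor)
                self.bad_epochs = 0


class EarlyStopper:
    """Stop when the validation loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best = math.inf
        self.best_epoch = -1
        self.epoch = -1

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; return True when training should stop."""
        self.epoch += 1
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.best_epoch = self.epoch
            return False
        return (self.epoch - self.best_epoch) >= self.patience
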