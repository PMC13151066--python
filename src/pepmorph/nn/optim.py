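"""Optimizers and learning-rate schedules for the sequence models."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter


class AdamW:
    """AdamW with decoupled weight decay; supports per-group learning rates.

    ``param_groups`` is a list of dicts with keys ``params`` (list of
    Parameters) and optional ``lr`` overriding the default.
    """

    def __init__(self, params_or_groups, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        if params_or_groups and isinstance(params_or_groups[0], Parameter):
            groups = [{"params": list(params_or_groups)}]
        else:
            groups = [dict(g) for g in params_or_groups]
        self.param_groups = []
        for g in groups:
            g.setdefault("lr", lr)
            self.param_groups.append(g)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def zero_grad(self) -> None:
        for g in self.param_groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for group in self.param_groups:
            lr = group["lr"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                m = self._m.get(key)
                if m is None:
                    m = self._m[key] = np.zeros_like(p.data)
                    self._v[key] = np.zeros_like(p.data)
                v = self._v[key]
                m *= self.beta1
                m += (1 - self.beta1) * p.grad
                v *= self.beta2
                v += (1 - self.beta2) * p.grad**2
                update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                if self.weight_decay:
                    p.data -= lr * self.weight_decay * p.data
                p.data -= lr * update

    def scale_lr(self, factor: float) -> None:
        for g in self.param_groups:
            g["lr"] *= factor


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: AdamW, factor: float = 0.5, patience: int = 30,
                 min_lr: float = 1e-6):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> bool:
        """Returns True if the LR was reduced this call."""
        if loss < self.best - 1e-12:
            self.best = loss
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.bad_epochs = 0
            for g in self.optimizer.param_groups:
                g["lr"] = max(g["lr"] * self.factor, self.min_lr)
            return True
        return False


class ExponentialDecay:
    """Multiply every group's LR by ``gamma`` each epoch."""

    def __init__(self, optimizer: AdamW, gamma: float = 0.9):
        self.optimizer = optimizer
        self.gamma = gamma

    def step(self) -> None:
        self.optimizer.scale_lr(self.gamma)


def cyclic_beta(epoch: int, period: int = 25, beta_max: float = 1.0,
                ramp_fraction: float = 0.5) -> float:
    """Cyclic KL-annealing weight: linear ramp to beta_max, then flat.

    Within each cycle of ``period`` epochs, beta rises linearly from 0 to
    ``beta_max`` over the first ``ramp_fraction`` of the cycle and stays at
    ``beta_max`` for the rest.
    """
    if period <= 0:
        return beta_max
    phase = (epoch % period) / period
    if phase < ramp_fraction:
        return beta_max * phase / ramp_fraction
    return beta_max
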