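"""Adam optimizer and the plateau learning-rate schedule used for training."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate after `patience` consecutive non-improving
    epochs, never dropping below `min_lr`; the counter resets whenever the
    monitored loss improves on its best value so far, and after a reduction.
    """

    def __init__(self, optimizer: Adam | None, lr_init: float | None = None,
                 factor: float = 0.5, patience: int = 5, min_lr: float = 1e-7):
        if not 0 < factor < 1:
            raise ValueError("factor must lie in (0, 1)")
        self.optimizer = optimizer
        self.lr = float(lr_init if lr_init is not None else optimizer.lr)
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> float:
        if loss < self.best:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
        if self.optimizer is not None:
            self.optimizer.lr = self.lr
        return self.lr


def plateau_schedule(loss_history: list[float], lr_init: float,
                     factor: float = 0.5, patience: int = 5,
                     min_lr: float = 1e-7) -> float:
    """Replay a loss history through the plateau schedule; return the final lr."""
    sched = ReduceLROnPlateau(None, lr_init=lr_init, factor=factor,
                              patience=patience, min_lr=min_lr)
    lr = lr_init
    for loss in loss_history:
        lr = sched.step(loss)
    return lr
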