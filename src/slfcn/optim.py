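"""First-order optimizer registry.

Each optimizer updates a flat {name: array} parameter dict in place from a
matching gradient dict.  Weight decay is applied as L2 regularisation added
to the gradient before the update rule.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_optimizer", "OPTIMIZERS"]


class _Optimizer:
    def __init__(self, lr: float, weight_decay: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be nonnegative")
        self.lr = lr
        self.weight_decay = weight_decay
        self.state: dict = {}

    def _slot(self, key, like):
        return self.state.setdefault(key, np.zeros_like(like))

    def step(self, params: dict, grads: dict):
        for key, theta in params.items():
            g = grads[key].astype(np.float32)
            if self.weight_decay:
                g = g + self.weight_decay * theta
            self._update(key, theta, g)

    def _update(self, key, theta, g):  # pragma: no cover
        raise NotImplementedError


class SGDMomentum(_Optimizer):
    """v <- mu*v - lr*g ; theta <- theta + v."""

    def __init__(self, lr, momentum=0.99, weight_decay=0.0):
        super().__init__(lr, weight_decay)
        if not 0 <= momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        self.momentum = momentum

    def _update(self, key, theta, g):
        v = self._slot(key, theta)
        v *= self.momentum
        v -= self.lr * g
        theta += v


class NAG(SGDMomentum):
    """Nesterov accelerated gradient (lookahead form of momentum SGD)."""

    def _update(self, key, theta, g):
        v = self._slot(key, theta)
        v *= self.momentum
        v -= self.lr * g
        theta += self.momentum * v - self.lr * g


class Adam(_Optimizer):
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0,
                 **_):
        super().__init__(lr, weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        super().step(params, grads)

    def _update(self, key, theta, g):
        m = self._slot(("m", key), theta)
        v = self._slot(("v", key), theta)
        m *= self.beta1
        m += (1 - self.beta1) * g
        v *= self.beta2
        v += (1 - self.beta2) * g * g
        mhat = m / (1 - self.beta1 ** self.t)
        vhat = v / (1 - self.beta2 ** self.t)
        theta -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adagrad(_Optimizer):
    def __init__(self, lr, eps=1e-10, weight_decay=0.0, **_):
        super().__init__(lr, weight_decay)
        self.eps = eps

    def _update(self, key, theta, g):
        acc = self._slot(key, theta)
        acc += g * g
        theta -= self.lr * g / (np.sqrt(acc) + self.eps)


class Adadelta(_Optimizer):
    def __init__(self, lr=1.0, rho=0.9, eps=1e-6, weight_decay=0.0, **_):
        super().__init__(lr, weight_decay)
        self.rho, self.eps = rho, eps

    def _update(self, key, theta, g):
        acc = self._slot(("acc", key), theta)
        delta_acc = self._slot(("delta", key), theta)
        acc *= self.rho
        acc += (1 - self.rho) * g * g
        update = g * np.sqrt(delta_acc + self.eps) / np.sqrt(acc + self.eps)
        delta_acc *= self.rho
        delta_acc += (1 - self.rho) * update * update
        theta -= self.lr * update


class RMSprop(_Optimizer):
    def __init__(self, lr, alpha=0.99, eps=1e-8, weight_decay=0.0, **_):
        super().__init__(lr, weight_decay)
        self.alpha, self.eps = alpha, eps

    def _update(self, key, theta, g):
        acc = self._slot(key, theta)
        acc *= self.alpha
        acc += (1 - self.alpha) * g * g
        theta -= self.lr * g / (np.sqrt(acc) + self.eps)


OPTIMIZERS = {
    "sgd_momentum": SGDMomentum,
    "nag": NAG,
    "adam": Adam,
    "adagrad": Adagrad,
    "adadelta": Adadelta,
    "rmsprop": RMSprop,
}


def make_optimizer(name: str, lr: float, momentum: float = 0.99,
                   weight_decay: float = 0.0) -> _Optimizer:
    if name not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; "
                         f"choose from {sorted(OPTIMIZERS)}")
    cls = OPTIMIZERS[name]
    if cls in (SGDMomentum, NAG):
        return cls(lr, momentum=momentum, weight_decay=weight_decay)
    return cls(lr, weight_decay=weight_decay)
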