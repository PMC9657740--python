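"""Training loop for the soft-label FCN.

Samples are visited one at a time (batch size 1, the FCN tradition for
full-field tiles); each step runs forward, evaluates the weighted softmax
loss and its gradient, backpropagates, and applies the chosen optimizer.
With the published settings (SGD momentum 0.99, lr 1e-10, sum reduction) the
loop reproduces the historical recipe; the desk-scale profile trains a
narrow network with mean reduction at an ordinary learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .loss import soft_weight_softmax_grad
from .network import SLFCN, initialize
from .optim import make_optimizer

__all__ = ["TrainConfig", "DESK_PROFILE", "fit"]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "sgd_momentum"
    lr: float = 1e-10
    momentum: float = 0.99
    weight_decay: float = 5e-4
    init: str | None = None
    steps: int = 100
    seed: int = 0
    reduction: str = "sum"
    shuffle: bool = True

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("learning rate must be nonnegative")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


#: Desk-scale profile: ordinary lr with mean reduction on a narrow network;
#: momentum stays at the published 0.99.
DESK_PROFILE = TrainConfig(optimizer="sgd_momentum", lr=1e-3, momentum=0.99,
                           weight_decay=5e-4, init="kaiming_bilinear",
                           steps=500, reduction="mean")


def fit(network: SLFCN, dataset, tc: TrainConfig):
    """Train in place; returns (network, loss_history).

    ``dataset`` is a sequence of ``(image (3,H,W) float, labels (H,W),
    weight_map (H,W))`` samples.  Deterministic given the seed under
    single-threaded execution.  Aborts with a diagnostic on NaN loss.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(tc.seed)
    if tc.init is not None:
        initialize(network, tc.init, seed=int(rng.integers(2**31)))
    network.set_rng(rng)
    opt = make_optimizer(tc.optimizer, tc.lr, momentum=tc.momentum,
                         weight_decay=tc.weight_decay)
    params = network.parameters()

    history = []
    order = np.arange(len(dataset))
    pos = len(order)  # force reshuffle on first step
    for step in range(tc.steps):
        if pos >= len(order):
            if tc.shuffle:
                rng.shuffle(order)
            pos = 0
        image, labels, weights = dataset[order[pos]]
        pos += 1

        scores = network.forward(np.asarray(image, np.float32), train=True)
        try:
            loss, dscores = soft_weight_softmax_grad(
                scores, labels, weights, reduction=tc.reduction)
        except FloatingPointError:
            loss = float("nan")
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss {loss!r} at step {step} "
                f"(lr={tc.lr}, optimizer={tc.optimizer}); "
                "reduce the learning rate or check the inputs")
        network.zero_grad()
        network.backward(dscores.astype(np.float32))
        opt.step(params, network.gradients())
        history.append(float(loss))
    return network, history
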