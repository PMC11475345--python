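"""SGD with momentum and decoupled-from-BN weight decay."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class SGD:
    """Stochastic gradient descent with classical momentum.

    Weight decay is applied only to parameters listed in ``decay_params``
    (convolution weights); biases and normalization affines are exempt,
    following common detector training practice.
    """

    def __init__(self, params, lr: float, momentum: float = 0.937, weight_decay: float = 0.0005, decay_params=None):
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        decay_ids = {id(p) for p in (decay_params if decay_params is not None else self.params)}
        self.decay_mask = [id(p) in decay_ids for p in self.params]
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v, decay in zip(self.params, self.velocity, self.decay_mask):
            if p.grad is None:
                continue
            g = p.grad
            if decay and self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
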