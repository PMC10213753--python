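"""Adam optimizer over the layer-parameter dictionaries."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, layers, lr: float = 0.003, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers
        ]

    def step(self) -> None:
        """Apply one update from the gradients currently stored on the layers."""
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * (g * g)
                p -= (self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)).astype(p.dtype)
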