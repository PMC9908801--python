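"""Adam optimizer (framework-default settings: lr 1e-3, betas 0.9/0.999)."""

from __future__ import annotations

import numpy as np

from .layers import F32, Layer


class Adam:
    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= (
                    self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
                ).astype(F32)
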