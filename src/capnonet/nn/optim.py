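"""Adam optimizer (Kingma & Ba) over the engine's layer parameters."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.layers = layers
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for key, p in layer.params.items():
                g = layer.grads[key]
                m[key] = self.b1 * m[key] + (1 - self.b1) * g
                v[key] = self.b2 * v[key] + (1 - self.b2) * g * g
                mhat = m[key] / bc1
                vhat = v[key] / bc2
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
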