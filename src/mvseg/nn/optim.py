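"""Adam optimizer over (value, gradient) parameter pairs."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(
        self,
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        """Update every parameter in place from its stored gradient."""
        if self._m is None:
            self._m = [np.zeros_like(p) for p, _ in params]
            self._v = [np.zeros_like(p) for p, _ in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(params, self._m, self._v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
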