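"""Adam optimizer operating in place on a flat parameter list."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam with bias-corrected first/second moments.

    ``params`` is a list of arrays that are updated *in place* so that the
    owning layers keep seeing the current values.  The learning rate can be
    changed between steps (plateau schedule).
    """

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params: List[np.ndarray] = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p, dtype=np.float32) for p in self.params]

    def step(self, grads: Sequence[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float32, copy=False)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)
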