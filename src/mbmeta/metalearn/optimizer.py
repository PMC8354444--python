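"""Minimal RMSprop (no optimizer library ships with the stack).

Canonical form: a running average of squared gradients normalizes each
update,

    v <- alpha v + (1 - alpha) g^2
    p <- p - lr * g / (sqrt(v) + eps)

with alpha = 0.99 and eps = 1e-8 by default.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RMSprop", "clip_gradients"]


def clip_gradients(grads: dict, max_norm: float) -> float:
    """Clip a gradient dict to a global norm, in place; returns the norm.

    Entries are first clamped elementwise (with non-finite values zeroed)
    so the norm itself cannot overflow; a single exploding unroll then
    perturbs the optimizer by at most ``max_norm`` instead of poisoning
    its running second-moment estimate.
    """
    total = 0.0
    for k, g in grads.items():
        g = np.clip(np.nan_to_num(np.asarray(g, dtype=float),
                                  nan=0.0, posinf=1e12, neginf=-1e12),
                    -1e12, 1e12)
        grads[k] = g
        total += float((g * g).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm:
        scale = max_norm / norm
        for k in grads:
            grads[k] = grads[k] * scale
    return norm


class RMSprop:
    """Updates a dict of parameter arrays in place."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.v = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for name, p in self.params.items():
            if name not in grads:   # parameter unused by this loss
                continue
            g = np.asarray(grads[name], dtype=p.dtype)
            v = self.v[name]
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)
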