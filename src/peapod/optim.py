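"""Adam optimiser with first/second-moment bias correction.

The update sequence per step t (for each parameter with gradient g):

    m_t = b1 m_{t-1} + (1 - b1) g          (first moment)
    v_t = b2 v_{t-1} + (1 - b2) g^2        (second moment)
    m^ = m_t / (1 - b1^t),  v^ = v_t / (1 - b2^t)
    theta <- theta - eta * m^ / (sqrt(v^) + eps)

Defaults follow the training setup used for the detector: b1 = 0.937
(the momentum hyperparameter), b2 = 0.999.
"""
from __future__ import annotations

from typing import Dict, List

import numpy as np

from .nn import Parameter

__all__ = ["Adam", "adam_step"]


class Adam:
    def __init__(self, params: List[Parameter], lr: float = 1e-2,
                 beta1: float = 0.937, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    # -- checkpointing ----------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        d = {"t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            d[f"m{i}"] = m
            d[f"v{i}"] = v
        return d

    def load_state_dict(self, d):
        self.t = int(d["t"])
        for i in range(len(self.m)):
            self.m[i] = np.asarray(d[f"m{i}"]).copy()
            self.v[i] = np.asarray(d[f"v{i}"]).copy()


def adam_step(params, grads, state=None, lr=1e-2, beta1=0.937, beta2=0.999,
              eps=1e-8):
    """Functional single step on plain arrays (convenience / oracle surface).

    ``state`` is ``(t, m, v)`` or None; returns ``(new_params, new_state)``.
    """
    params = [np.asarray(p, dtype=np.float64) for p in params]
    grads = [np.asarray(g, dtype=np.float64) for g in grads]
    if any(p.shape != g.shape for p, g in zip(params, grads)) or \
            len(params) != len(grads):
        raise ValueError("parameter/gradient shape mismatch")
    if state is None:
        state = (0, [np.zeros_like(p) for p in params],
                 [np.zeros_like(p) for p in params])
    t, m, v = state
    t += 1
    new_p, new_m, new_v = [], [], []
    for p, g, mi, vi in zip(params, grads, m, v):
        mi = beta1 * mi + (1 - beta1) * g
        vi = beta2 * vi + (1 - beta2) * g * g
        mhat = mi / (1 - beta1**t)
        vhat = vi / (1 - beta2**t)
        new_p.append(p - lr * mhat / (np.sqrt(vhat) + eps))
        new_m.append(mi)
        new_v.append(vi)
    return new_p, (t, new_m, new_v)
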