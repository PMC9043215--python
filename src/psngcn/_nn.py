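"""Small neural-network primitives shared by the DAE and the DenseGCN."""

from __future__ import annotations

import numpy as np

try:  # fused single-pass update; falls back to plain numpy without numba
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _adam_kernel(p, g, m, v, b1, one_m_b1, b2, one_m_b2, lr1, k2, eps, tiny):
        # p -= (lr/c1) * m / (sqrt(v)/sqrt(c2) + eps), scalars pre-hoisted.
        # Moments for long-dead weights decay geometrically into the
        # subnormal range, where float arithmetic stalls by orders of
        # magnitude; flush them to zero well before that.
        for i in range(p.size):  # pragma: no cover
            gi = g[i]
            mi = b1 * m[i] + one_m_b1 * gi
            vi = b2 * v[i] + one_m_b2 * gi * gi
            if -tiny < mi < tiny:
                mi = 0.0
            if vi < tiny:
                vi = 0.0
            m[i] = mi
            v[i] = vi
            p[i] -= lr1 * mi / (np.sqrt(vi) * k2 + eps)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # exp overflow for very negative x saturates to inf -> 1/inf = 0, correct
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adaptive-moment gradient descent over a dict of named parameter arrays.

    Parameters are updated in place so callers can keep references. With many
    parameters and tiny mini-batches the update itself dominates runtime, so
    the per-element recursion is fused into one pass when numba is available.
    """

    def __init__(self, params: dict, lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for k, g in grads.items():
            p = self.params[k]
            g = np.ascontiguousarray(g, dtype=p.dtype)
            if _HAVE_NUMBA:
                # scalars in the parameter dtype so the kernel vectorizes
                s = p.dtype.type
                _adam_kernel(p.ravel(), g.ravel(), self.m[k].ravel(),
                             self.v[k].ravel(), s(b1), s(1 - b1), s(b2),
                             s(1 - b2), s(self.lr / c1), s(1 / np.sqrt(c2)),
                             s(self.eps), s(1e-24))
            else:
                m = self.m[k]
                v = self.v[k]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                denom = np.sqrt(v / c2)
                denom += self.eps
                p -= (self.lr / c1) * m / denom
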