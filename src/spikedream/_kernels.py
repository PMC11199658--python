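"""Fused inner-loop kernels for the online updates.

The per-step cost of online training is dominated by elementwise passes
over the N×N recurrent matrices (moment updates and discounted eligibility
accumulation).  These kernels fuse each pass; when numba is importable they
are JIT-compiled, otherwise plain NumPy equivalents are used.  Both paths
compute the same expressions in the same order.

Gradients come in three structural forms exploited here: dense arrays,
rank-1 outer products (three-factor rules), and exact zeros (reward-gated
rules on zero-reward steps, where only the moment decay acts).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _adam_dense_nb(p, g, m, v, lr, b1, b2, eps, bc1, bc2):
    for i in range(p.size):
        m[i] = b1 * m[i] + (1.0 - b1) * g[i]
        v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
        p[i] += lr * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)


@njit(cache=False)
def _adam_zero_nb(p, m, v, lr, b1, b2, eps, bc1, bc2):
    for i in range(p.size):
        m[i] = b1 * m[i]
        v[i] = b2 * v[i]
        p[i] += lr * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)


@njit(cache=False)
def _adam_rank1_nb(p, a, b, m, v, lr, b1, b2, eps, bc1, bc2):
    n, k = p.shape
    for i in range(n):
        ai = a[i]
        for j in range(k):
            g = ai * b[j]
            m[i, j] = b1 * m[i, j] + (1.0 - b1) * g
            v[i, j] = b2 * v[i, j] + (1.0 - b2) * g * g
            p[i, j] += lr * (m[i, j] / bc1) / (np.sqrt(v[i, j] / bc2) + eps)


@njit(cache=False)
def _rank1_discount_nb(acc, gamma, a, b):
    n, k = acc.shape
    for i in range(n):
        ai = a[i]
        for j in range(k):
            acc[i, j] = gamma * acc[i, j] + ai * b[j]


def _adam_dense_np(p, g, m, v, lr, b1, b2, eps, bc1, bc2):
    m *= b1
    m += (1.0 - b1) * g
    v *= b2
    v += (1.0 - b2) * np.square(g)
    p += lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


def _adam_zero_np(p, m, v, lr, b1, b2, eps, bc1, bc2):
    m *= b1
    v *= b2
    p += lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


def _adam_rank1_np(p, a, b, m, v, lr, b1, b2, eps, bc1, bc2):
    _adam_dense_np(p, np.outer(a, b), m, v, lr, b1, b2, eps, bc1, bc2)


def _rank1_discount_np(acc, gamma, a, b):
    acc *= gamma
    acc += np.outer(a, b)


def adam_dense(p, g, m, v, lr, b1, b2, eps, bc1, bc2):
    """One bias-corrected moment update with a dense gradient, in place."""
    if HAVE_NUMBA and p.flags.c_contiguous and g.flags.c_contiguous:
        _adam_dense_nb(p.reshape(-1), g.reshape(-1), m.reshape(-1), v.reshape(-1),
                       lr, b1, b2, eps, bc1, bc2)
    else:
        _adam_dense_np(p, g, m, v, lr, b1, b2, eps, bc1, bc2)


def adam_zero(p, m, v, lr, b1, b2, eps, bc1, bc2):
    """Moment update with an exactly-zero gradient (decay + drift only)."""
    if HAVE_NUMBA and p.flags.c_contiguous:
        _adam_zero_nb(p.reshape(-1), m.reshape(-1), v.reshape(-1),
                      lr, b1, b2, eps, bc1, bc2)
    else:
        _adam_zero_np(p, m, v, lr, b1, b2, eps, bc1, bc2)


def adam_rank1(p, a, b, m, v, lr, b1, b2, eps, bc1, bc2):
    """Moment update with the rank-1 gradient g = a ⊗ b, never materialised."""
    if HAVE_NUMBA and p.flags.c_contiguous:
        _adam_rank1_nb(p, np.ascontiguousarray(a), np.ascontiguousarray(b),
                       m, v, lr, b1, b2, eps, bc1, bc2)
    else:
        _adam_rank1_np(p, a, b, m, v, lr, b1, b2, eps, bc1, bc2)


def rank1_discount(acc, gamma, a, b):
    """Discounted eligibility accumulation acc ← γ·acc + a ⊗ b, in place."""
    if HAVE_NUMBA and acc.flags.c_contiguous:
        _rank1_discount_nb(acc, gamma, np.ascontiguousarray(a), np.ascontiguousarray(b))
    else:
        _rank1_discount_np(acc, gamma, a, b)
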