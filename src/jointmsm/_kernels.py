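"""Closed-form interval transition probabilities, vectorized.

Both model structures used here admit exact closed forms for ``exp(Q t)``:

* the progressive four-state chain 1->{2,3}->4 (upper-triangular generator
  with distinct exponential stages), and
* the three-state chain with reversible 1<->2 and absorbing 3, whose
  restriction to the transient states is a 2x2 matrix with real eigenvalues.

These kernels are the numerical core of the fitting engines; the generic
``scipy.linalg.expm`` route in :mod:`jointmsm.ctmc` serves as the reference
implementation and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

_TINY = 1e-300


def phi(x: np.ndarray) -> np.ndarray:
    """``(exp(x) - 1) / x``, continuous and positive, stable near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 + 0.5 * x[small]
    xs = x[~small]
    out[~small] = np.expm1(xs) / xs
    return out


def progressive4_probs(q12, q13, q24, q34, dt):
    """Transition probabilities of the four-state progressive damage chain.

    All arguments broadcast; rates must already include any frailty or
    covariate scaling.  Returns a dict keyed by (from, to) with the
    nonzero entries; rows sum to one exactly by construction.
    """
    q12, q13, q24, q34, dt = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (q12, q13, q24, q34, dt))
    )
    a = q12 + q13
    p11 = np.exp(-a * dt)
    p12 = q12 * dt * p11 * phi((a - q24) * dt)
    p13 = q13 * dt * p11 * phi((a - q34) * dt)
    p14 = np.clip(1.0 - p11 - p12 - p13, 0.0, 1.0)
    p22 = np.exp(-q24 * dt)
    p33 = np.exp(-q34 * dt)
    return {
        (1, 1): p11, (1, 2): p12, (1, 3): p13, (1, 4): p14,
        (2, 2): p22, (2, 4): 1.0 - p22,
        (3, 3): p33, (3, 4): 1.0 - p33,
        (4, 4): np.ones_like(p11),
    }


def progressive4_logprob(q12, q13, q24, q34, dt, from_state, to_state):
    """Log interval probability for observed (from, to) pairs, vectorized."""
    P = progressive4_probs(q12, q13, q24, q34, dt)
    from_state = np.asarray(from_state)
    to_state = np.asarray(to_state)
    out = np.full(np.broadcast(from_state, to_state, P[(1, 1)]).shape, -np.inf)
    for (i, j), p in P.items():
        mask = (from_state == i) & (to_state == j)
        if np.any(mask):
            out = np.where(mask, np.log(np.maximum(p, _TINY)), out)
    return out


def threestate_transient(q12, q21, q13, q23, dt):
    """Entries of ``exp(M t)`` for the 2x2 transient block of the 3-state chain.

    ``M = [[-(q12+q13), q12], [q21, -(q21+q23)]]`` has real eigenvalues
    ``T/2 +- h`` with ``h = sqrt(((m11-m22)/2)^2 + q12*q21) >= 0``; both
    ``exp((T/2 +- h) t)`` lie in (0, 1], so the evaluation cannot overflow.

    Returns ``(p11, p12, p21, p22)``; absorption probabilities follow as
    ``p13 = 1 - p11 - p12`` and ``p23 = 1 - p21 - p22``.
    """
    q12, q21, q13, q23, dt = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (q12, q21, q13, q23, dt))
    )
    m11 = -(q12 + q13)
    m22 = -(q21 + q23)
    half_diff = 0.5 * (m11 - m22)
    half_tr = 0.5 * (m11 + m22)
    h = np.sqrt(half_diff ** 2 + q12 * q21)
    e1 = np.exp((half_tr + h) * dt)
    e2 = np.exp((half_tr - h) * dt)
    C = 0.5 * (e1 + e2)
    # G = t * e^{T t/2} sinh(h t)/(h t); series branch for the defective limit
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(h * dt < 1e-8, dt * e1, (e1 - e2) / np.where(h > 0, 2 * h, 1.0))
    p11 = C + G * half_diff
    p12 = G * q12
    p21 = G * q21
    p22 = C - G * half_diff
    return p11, p12, p21, p22


def threestate_matrix(q12, q21, q13, q23, dt):
    """Full row-stochastic 3x3 matrices, shape ``(..., 3, 3)``."""
    p11, p12, p21, p22 = threestate_transient(q12, q21, q13, q23, dt)
    shape = p11.shape
    P = np.zeros(shape + (3, 3))
    P[..., 0, 0] = p11
    P[..., 0, 1] = p12
    P[..., 0, 2] = np.clip(1.0 - p11 - p12, 0.0, 1.0)
    P[..., 1, 0] = p21
    P[..., 1, 1] = p22
    P[..., 1, 2] = np.clip(1.0 - p21 - p22, 0.0, 1.0)
    P[..., 2, 2] = 1.0
    return P


def threestate_logprob(q12, q21, q13, q23, dt, from_state, to_state):
    """Log interval probability for the 3-state chain, vectorized."""
    p11, p12, p21, p22 = threestate_transient(q12, q21, q13, q23, dt)
    p13 = np.clip(1.0 - p11 - p12, 0.0, 1.0)
    p23 = np.clip(1.0 - p21 - p22, 0.0, 1.0)
    table = {
        (1, 1): p11, (1, 2): p12, (1, 3): p13,
        (2, 1): p21, (2, 2): p22, (2, 3): p23,
    }
    from_state = np.asarray(from_state)
    to_state = np.asarray(to_state)
    out = np.full(np.broadcast(from_state, to_state, p11).shape, -np.inf)
    for (i, j), p in table.items():
        mask = (from_state == i) & (to_state == j)
        if np.any(mask):
            out = np.where(mask, np.log(np.maximum(p, _TINY)), out)
    return out
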