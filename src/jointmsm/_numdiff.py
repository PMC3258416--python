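"""Central finite-difference derivatives.

Step size follows ``step * (1 + |x_i|)`` per coordinate.  Used for the
numerically derived Hessian at the optimum, for per-patient score vectors,
and for independent gradient checks in the tests.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def _steps(x: np.ndarray, rel_step: float) -> np.ndarray:
    return rel_step * (1.0 + np.abs(x))


def fd_gradient(f: Callable, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2 * h[i])
    return g


def fd_jacobian(f: Callable, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of a vector-valued function, shape (m, n).

    Used for per-patient score matrices: ``f`` returns the vector of
    per-patient log-likelihood contributions.
    """
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    cols = []
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        cols.append((np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2 * h[i]))
    return np.stack(cols, axis=1)


def fd_hessian(f: Callable, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function (symmetric by design)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = _steps(x, rel_step)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H
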