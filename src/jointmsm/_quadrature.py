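"""Quadrature rules for integrating over the gamma frailty distribution.

The marginal likelihood integrates a product of path probabilities against a
gamma(1/theta, 1/theta) density (unit mean, variance theta).  The default
rule is generalized Gauss-Laguerre with the gamma weight absorbed exactly by
the change of variable ``u = theta * x`` (weight ``x^{1/theta-1} e^{-x}``);
weights are normalized to sum to one, which sidesteps the Gamma(1/theta)
factor.  For very small theta the generalized-Laguerre weights overflow
double precision, so the rule falls back to Gauss-Legendre on the gamma CDF
(probability integral transform), which is uniformly stable in theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import gammaincinv, roots_genlaguerre


@dataclass(frozen=True)
class QuadratureConfig:
    n_nodes: int = 30
    method: str = "genlaguerre"  # "genlaguerre" | "cdf"


def gamma_quadrature(
    theta: float, n_nodes: int = 30, method: str = "genlaguerre"
) -> Tuple[np.ndarray, np.ndarray]:
    """Nodes and weights for ``E[g(U)]`` with ``U ~ gamma(1/theta, 1/theta)``.

    Returns ``(u, w)`` with ``sum(w) == 1``; ``E[g(U)] ~= sum(w * g(u))``.
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if method == "genlaguerre":
        alpha = 1.0 / theta - 1.0
        if alpha < 1e8:  # polynomial recurrences degrade far beyond this
            with np.errstate(over="ignore"):
                x, w = roots_genlaguerre(n_nodes, alpha)
            if np.all(np.isfinite(w)) and w.sum() > 0:
                return theta * x, w / w.sum()
        method = "cdf"  # overflow fallback for tiny theta
    if method == "cdf":
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        p = 0.5 * (x + 1.0)
        shape = 1.0 / theta
        u = theta * gammaincinv(shape, p)
        return u, 0.5 * w
    raise ValueError(f"unknown quadrature method {method!r}")
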