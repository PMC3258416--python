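"""Time-homogeneous CTMC machinery for panel-observed multistate processes.

Transition times are interval-censored at clinic visits, so the likelihood of
an observed path is a product of matrix-exponential transition probabilities
over consecutive visit pairs.  Covariates are piecewise constant between
visits: the interval ``(t_j, t_{j+1}]`` uses the values observed at visit
``j`` (covariates change state immediately after a visit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .exceptions import DataValidityError, SpecError
from .model_spec import ParameterSet, TransitionModelSpec, resolve_parameters

_TINY = 1e-300


@dataclass
class PanelPath:
    """One process's panel observations: visit times, states and covariates.

    ``covariates[j]`` holds the covariate values observed at visit ``j``;
    they drive the intensities over the following interval.
    """

    times: Sequence[float]
    states: Sequence[int]
    covariates: Sequence[Mapping[str, float]] = field(default_factory=tuple)
    joint_location: Optional[str] = None

    def __post_init__(self):
        self.times = tuple(float(t) for t in self.times)
        self.states = tuple(int(s) for s in self.states)
        if len(self.times) != len(self.states):
            raise DataValidityError("times and states differ in length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise DataValidityError("visit times must be strictly increasing")
        if not self.covariates:
            self.covariates = tuple({} for _ in self.times)
        if len(self.covariates) != len(self.times):
            raise DataValidityError("one covariate record per visit is required")

    @property
    def n_visits(self) -> int:
        return len(self.times)

    def validate(self, spec: TransitionModelSpec) -> None:
        bad = set(self.states) - set(spec.states)
        if bad:
            raise DataValidityError(f"states {sorted(bad)} outside the state space")


def intensity_matrix(
    spec: TransitionModelSpec,
    params: ParameterSet,
    frailty_u: float = 1.0,
    covariates: Optional[Mapping[str, float]] = None,
    joint_location: Optional[str] = None,
    epoch_time: float = 0.0,
) -> np.ndarray:
    """Generator matrix Q with entries ``u * lambda0_ij * exp(beta'z)``.

    The frailty ``u`` multiplies every transition intensity of the process;
    rows sum to zero and disallowed transitions are exactly zero.
    """
    if not frailty_u > 0:
        raise ValueError(f"frailty must be positive, got {frailty_u}")
    lam = resolve_parameters(spec, params, joint_location, covariates, epoch_time)
    n = len(spec.states)
    index = {s: i for i, s in enumerate(spec.states)}
    Q = np.zeros((n, n))
    for (i, j), rate in lam.items():
        Q[index[i], index[j]] = frailty_u * rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probability(Q: np.ndarray, dt: float) -> np.ndarray:
    """Interval transition probability matrix ``P(dt) = exp(Q * dt)``.

    Uses scipy's scaling-and-squaring Pade matrix exponential; entries are
    clipped into [0, 1] to remove rounding residue.
    """
    Q = np.asarray(Q, dtype=float)
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal intensities must be nonnegative")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-8 * (1 + np.abs(Q).max())):
        raise ValueError("rows of an intensity matrix must sum to zero")
    if dt == 0:
        return np.eye(Q.shape[0])
    P = expm(Q * dt)
    return np.clip(P, 0.0, 1.0)


def _reachability(spec: TransitionModelSpec) -> np.ndarray:
    """Boolean matrix: can state j be reached from i in positive time."""
    n = len(spec.states)
    index = {s: i for i, s in enumerate(spec.states)}
    A = np.eye(n, dtype=bool)
    for (i, j) in spec.allowed_transitions:
        A[index[i], index[j]] = True
    R = A.copy()
    for _ in range(n):
        R = R | (R @ A)
    return R


def path_probability(
    spec: TransitionModelSpec,
    params: ParameterSet,
    path: PanelPath,
    frailty_u: float = 1.0,
    return_log: bool = False,
) -> float:
    """Probability of a panel path conditional on its first observed state.

    The product over consecutive visit pairs of ``[P(dt)]_{s_j, s_{j+1}}``,
    with each interval's generator built from the covariates observed at the
    interval's left endpoint.  Accumulated in log space.  An observed
    transition that is structurally impossible (e.g. damage reversal) raises
    :class:`DataValidityError`.
    """
    path.validate(spec)
    index = {s: i for i, s in enumerate(spec.states)}
    reach = _reachability(spec)
    logp = 0.0
    for j in range(path.n_visits - 1):
        a, b = path.states[j], path.states[j + 1]
        if not reach[index[a], index[b]]:
            raise DataValidityError(
                f"observed transition {a}->{b} is impossible under the model "
                f"(visit {j}->{j + 1})"
            )
        dt = path.times[j + 1] - path.times[j]
        Q = intensity_matrix(
            spec, params, frailty_u, path.covariates[j], path.joint_location,
            epoch_time=path.times[j],
        )
        P = transition_probability(Q, dt)
        logp += float(np.log(max(P[index[a], index[b]], _TINY)))
    return logp if return_log else float(np.exp(logp))
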