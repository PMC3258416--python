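"""Working-independence fitting of the three-state activity-damage model.

The 28 hand-joint processes of a patient are correlated, but with reversible
activity transitions a shared random effect is computationally unattractive.
Instead the model is fitted as if the joints were independent (the working
independence likelihood) and the covariance of the estimates is corrected
with the robust information sandwich ``A^{-1} B A^{-1}``, where ``A`` is the
observed information of the total negative log-likelihood and ``B`` the sum
of outer products of per-patient score vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from ._likelihood import ThreeStateEngine
from ._numdiff import fd_gradient, fd_hessian, fd_jacobian
from .exceptions import FitError, SpecError
from .fit_result import FittedModel
from .frailty import OptimizerConfig
from .model_spec import ParameterSet, TransitionModelSpec, build_three_state_spec
from .panel_io import PanelDataset

__all__ = [
    "SandwichCovariance",
    "sandwich_covariance",
    "fit_three_state",
    "epoch_stratified_fit",
    "wald_test",
    "ThreeStateMarkovModel",
]


@dataclass
class SandwichCovariance:
    """Bread (observed information), meat (score outer products) and sandwich."""

    bread: np.ndarray
    meat: np.ndarray
    covariance: np.ndarray
    condition_number: float


def sandwich_covariance(scores: np.ndarray, hessian: np.ndarray) -> SandwichCovariance:
    """Robust covariance ``A^{-1} B A^{-1}`` from per-patient scores.

    ``scores`` has one row per patient (gradient of that patient's
    log-likelihood contribution at the MLE); ``hessian`` is the Hessian of
    the total negative log-likelihood at the same point.  Solved with a
    symmetric linear solve rather than an explicit inverse; an
    ill-conditioned information matrix triggers a warning carrying its
    condition number.
    """
    scores = np.asarray(scores, dtype=float)
    A = np.asarray(hessian, dtype=float)
    if scores.ndim != 2 or A.shape != (scores.shape[1], scores.shape[1]):
        raise ValueError(
            f"dimension mismatch: scores {scores.shape}, hessian {A.shape}"
        )
    cond = float(np.linalg.cond(A))
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            f"information matrix nearly singular (condition number {cond:.3g})",
            stacklevel=2,
        )
    B = scores.T @ scores
    try:
        Ainv_B = np.linalg.solve(A, B)
        cov = np.linalg.solve(A, Ainv_B.T).T
    except np.linalg.LinAlgError as err:
        raise FitError(
            f"singular information matrix (condition number {cond:.3g})"
        ) from err
    cov = 0.5 * (cov + cov.T)
    return SandwichCovariance(
        bread=A, meat=0.5 * (B + B.T), covariance=cov, condition_number=cond
    )


def fit_three_state(
    dataset: PanelDataset,
    spec: TransitionModelSpec,
    init: Optional[ParameterSet] = None,
    optimizer_config: Optional[OptimizerConfig] = None,
    exact_epoch_split: bool = False,
    compute_robust: bool = True,
) -> FittedModel:
    """Maximize the working-independence likelihood over all 28-joint panels.

    Each joint's follow-up is truncated at its first visit with observed
    damage (observation of the process stops when damage occurs); patients
    with unrecorded activity are removed (complete-case).  Returns naive
    (inverse-information) and robust (sandwich) covariances; the per-patient
    score matrix is kept on the result for inspection.
    """
    cfg = optimizer_config or OptimizerConfig()
    engine = ThreeStateEngine(dataset, spec, exact_epoch_split=exact_epoch_split)
    x0 = spec.flatten(init) if init is not None else engine.crude_initial_vector()

    def negll(x: np.ndarray) -> float:
        val = -engine.total_loglik(x)
        return val if np.isfinite(val) else 1e15

    res = optimize.minimize(
        negll, x0, method=cfg.method,
        jac=lambda x: fd_gradient(negll, x, cfg.grad_step),
        options={"gtol": cfg.gtol, "maxiter": cfg.maxiter},
    )
    x = res.x
    H = fd_hessian(negll, x, cfg.hessian_step)
    try:
        cov_naive = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_naive = np.linalg.pinv(H)
    cov_naive = 0.5 * (cov_naive + cov_naive.T)

    scores = None
    cov_robust = None
    if compute_robust:
        scores = fd_jacobian(engine.patient_loglik, x, cfg.score_step)
        cov_robust = sandwich_covariance(scores, H).covariance

    return FittedModel(
        spec=spec,
        params=spec.unflatten(x),
        x=x,
        param_names=spec.parameter_names,
        loglik=float(-negll(x)),
        hessian=H,
        cov_naive=cov_naive,
        cov_robust=cov_robust,
        converged=bool(res.success),
        n_patients=engine.n_patients,
        message=str(res.message),
        boundary_flags=[],
        scores=scores,
    )


def epoch_stratified_fit(
    dataset: PanelDataset,
    spec: TransitionModelSpec,
    **kwargs,
) -> FittedModel:
    """Fit a three-state model with piecewise-constant time epochs.

    ``spec`` must carry epoch cut times (see
    :func:`~jointmsm.model_spec.build_three_state_spec`); with every epoch
    effect constrained to zero the log-likelihood reduces exactly to the
    homogeneous model's.  Epochs with no observation time are flagged as
    unidentifiable via the information-matrix condition warning.
    """
    if not spec.time_epochs:
        raise SpecError("epoch_stratified_fit requires a spec with time_epochs")
    return fit_three_state(dataset, spec, **kwargs)


def wald_test(
    fitted: FittedModel,
    contrast,
    use_robust: bool = True,
):
    """Wald test of ``C @ params = 0`` against chi-square with rank(C) df.

    ``contrast`` is a vector (single linear combination) or matrix with one
    row per combination.  For a single parameter the statistic reduces to
    ``(estimate / SE)^2``.  Returns ``(statistic, df, p_value)``.
    """
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    p = len(fitted.x)
    if C.shape[1] != p:
        raise ValueError(f"contrast has {C.shape[1]} columns, expected {p}")
    cov = fitted._cov(use_robust)
    V = C @ cov @ C.T
    est = C @ fitted.x
    df = int(np.linalg.matrix_rank(C))
    if np.allclose(np.diag(V), 0.0):
        raise FitError("zero-variance contrast")
    if np.allclose(est, 0.0):
        return 0.0, df, 1.0
    try:
        stat = float(est @ np.linalg.solve(V, est))
    except np.linalg.LinAlgError:
        stat = float(est @ np.linalg.pinv(V) @ est)
    return stat, df, float(chi2.sf(stat, df))


class ThreeStateMarkovModel(BaseEstimator):
    """Three-state activity-damage model with robust sandwich covariance.

    scikit-learn style estimator over a long-format panel; ``fit(X)`` stores
    the :class:`FittedModel` in ``result_`` with both naive and robust
    confidence intervals available from ``summary(robust=...)``.
    """

    def __init__(
        self,
        joint_type_factor: bool = False,
        ever_active: bool = False,
        opposite_damage: bool = False,
        gamma_reparam: bool = True,
        time_epochs: Optional[Sequence[float]] = None,
        epoch_transitions: Optional[Sequence] = None,
        joint_type_reference: str = "MCP",
        exact_epoch_split: bool = False,
        gtol: float = 1e-5,
        maxiter: int = 500,
    ):
        self.joint_type_factor = joint_type_factor
        self.ever_active = ever_active
        self.opposite_damage = opposite_damage
        self.gamma_reparam = gamma_reparam
        self.time_epochs = time_epochs
        self.epoch_transitions = epoch_transitions
        self.joint_type_reference = joint_type_reference
        self.exact_epoch_split = exact_epoch_split
        self.gtol = gtol
        self.maxiter = maxiter

    def _as_dataset(self, X) -> PanelDataset:
        return X if isinstance(X, PanelDataset) else PanelDataset(X)

    def fit(self, X, y=None):
        ds = self._as_dataset(X)
        self.spec_ = build_three_state_spec(
            joint_type_factor=self.joint_type_factor,
            ever_active=self.ever_active,
            opposite_damage=self.opposite_damage,
            gamma_reparam=self.gamma_reparam,
            time_epochs=self.time_epochs,
            epoch_transitions=self.epoch_transitions,
            joint_type_reference=self.joint_type_reference,
        )
        self.result_ = fit_three_state(
            ds, self.spec_,
            optimizer_config=OptimizerConfig(gtol=self.gtol, maxiter=self.maxiter),
            exact_epoch_split=self.exact_epoch_split,
        )
        self.params_ = self.result_.params
        self.loglik_ = self.result_.loglik
        self.converged_ = self.result_.converged
        self.n_parameters_ = self.spec_.n_parameters
        if self.gamma_reparam:
            i = self.result_.param_names.index("gamma")
            self.gamma_ = float(self.result_.x[i])
            self.intensity_ratio_ = float(np.exp(self.gamma_))
        return self

    def score(self, X, y=None) -> float:
        ds = self._as_dataset(X)
        engine = ThreeStateEngine(ds, self.spec_, self.exact_epoch_split)
        return float(np.mean(engine.patient_loglik(self.result_.x)))

    def summary(self, robust: bool = True) -> pd.DataFrame:
        return self.result_.summary_table(robust)
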