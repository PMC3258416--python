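"""Marginal maximum likelihood for the four-state paired-damage model.

A patient's 14 joint-location damage processes share one multiplicative
gamma frailty U ~ gamma(1/theta, 1/theta) (unit mean, variance theta), which
induces the within-patient correlation.  The patient's likelihood
contribution integrates the product of the 14 conditional path probabilities
over the frailty distribution; the integral is evaluated by Gaussian
quadrature (see :mod:`jointmsm._quadrature`) and maximized by BFGS on the
unconstrained (log-intensity / log-theta) parameter vector.  Standard errors
come from the numerically derived Hessian at the optimum; the frailty
variance interval is formed on the log scale and exponentiated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist, norm
from sklearn.base import BaseEstimator

from ._likelihood import FourStateEngine
from ._numdiff import fd_gradient, fd_hessian
from ._quadrature import QuadratureConfig, gamma_quadrature
from .ctmc import PanelPath, path_probability
from .exceptions import FitError, SpecError
from .fit_result import FittedModel
from .model_spec import (
    ParameterSet,
    TransitionModelSpec,
    build_four_state_spec,
)
from .panel_io import PanelDataset

__all__ = [
    "FrailtyDistribution",
    "frailty_density",
    "marginal_patient_loglik",
    "fit_frailty_model",
    "symmetry_test",
    "FourStateFrailtyModel",
    "OptimizerConfig",
]


@dataclass(frozen=True)
class OptimizerConfig:
    method: str = "BFGS"
    gtol: float = 1e-5
    maxiter: int = 500
    grad_step: float = 1e-6
    hessian_step: float = 1e-5
    score_step: float = 1e-6
    cross_check_quadrature: bool = True


def frailty_density(u, theta: float):
    """Density of the unit-mean gamma frailty: shape 1/theta, rate 1/theta."""
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0):
        raise ValueError("frailty density is defined for u > 0 only")
    out = gamma_dist.pdf(u_arr, a=1.0 / theta, scale=theta)
    return float(out) if np.isscalar(u) or u_arr.ndim == 0 else out


class FrailtyDistribution:
    """Unit-mean gamma frailty with variance ``theta`` (shape = rate = 1/theta)."""

    def __init__(self, theta: float):
        if theta <= 0:
            raise ValueError(f"theta must be positive, got {theta}")
        self.theta = float(theta)

    @property
    def shape(self) -> float:
        return 1.0 / self.theta

    @property
    def rate(self) -> float:
        return 1.0 / self.theta

    @property
    def mean(self) -> float:
        return 1.0

    @property
    def variance(self) -> float:
        return self.theta

    def density(self, u):
        return frailty_density(u, self.theta)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(shape=self.shape, scale=self.theta, size=size)


def marginal_patient_loglik(
    spec: TransitionModelSpec,
    params: ParameterSet,
    paths: Sequence[PanelPath],
    theta: Optional[float] = None,
    quadrature: Optional[QuadratureConfig] = None,
) -> float:
    """Log marginal likelihood of one patient's joint-location paths.

    ``log Int_0^inf prod_l P(path_l | u) f(u; theta) du`` with ``f`` the
    unit-mean gamma density.  Reference implementation built on
    :func:`jointmsm.ctmc.path_probability`; the fitting engine evaluates the
    same quantity vectorized (the two are cross-checked in the tests).

    ``quadrature.method == "adaptive"`` integrates with ``scipy.integrate.quad``
    and raises :class:`FitError` with diagnostics if the integrator reports
    non-convergence.
    """
    if theta is None:
        theta = params.theta
    if theta is None:
        raise SpecError("theta required: pass it or include log_theta in params")
    quadrature = quadrature or QuadratureConfig()

    def joint_logprob(u: float) -> float:
        return sum(
            path_probability(spec, params, p, frailty_u=u, return_log=True)
            for p in paths
        )

    if quadrature.method == "adaptive":
        shift = joint_logprob(1.0)
        val, err, info = integrate.quad(
            lambda u: np.exp(joint_logprob(u) - shift) * frailty_density(u, theta),
            0.0, np.inf, full_output=True,
        )[:3]
        if val <= 0 or err > 1e-8 * max(val, 1e-10):
            raise FitError(
                f"adaptive frailty integration unreliable: value={val}, "
                f"abs. error estimate={err}, evaluations={info['neval']}"
            )
        return float(np.log(val) + shift)

    u, w = gamma_quadrature(theta, quadrature.n_nodes, quadrature.method)
    logs = np.array([joint_logprob(ui) for ui in u])
    return float(logsumexp(np.log(w) + logs))


def _boundary_flags(spec: TransitionModelSpec, x: np.ndarray) -> list:
    flags = []
    names = spec.parameter_names
    for i, name in enumerate(names):
        if name in spec.baseline_names and x[i] < np.log(1e-8):
            flags.append(f"baseline {name} at zero boundary")
        if name == "log_theta" and x[i] < np.log(1e-4):
            flags.append("frailty variance theta at zero boundary")
    return flags


def _invert_information(H: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            f"observed information is ill-conditioned (condition number {cond:.3g}); "
            "standard errors may be unreliable",
            stacklevel=3,
        )
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return 0.5 * (cov + cov.T)


def fit_frailty_model(
    dataset: PanelDataset,
    spec: TransitionModelSpec,
    init: Optional[ParameterSet] = None,
    optimizer_config: Optional[OptimizerConfig] = None,
    quadrature: Optional[QuadratureConfig] = None,
) -> FittedModel:
    """Maximize the marginal likelihood over all patients.

    If the covariate design uses activity, patients with unrecorded activity
    are removed first (complete-case at patient level; never imputed).
    Boundary solutions (an intensity or theta heading to zero) are flagged in
    ``result.boundary_flags`` rather than masked.
    """
    cfg = optimizer_config or OptimizerConfig()
    quadrature = quadrature or QuadratureConfig()
    if any(e.role != "time-epoch" for e in spec.covariate_design):
        dataset, _excluded = dataset.complete_case()
    engine = FourStateEngine(dataset, spec, quadrature)
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
    loglik = engine.total_loglik(x)

    if cfg.cross_check_quadrature and spec.frailty:
        # refinement check: doubling the node count must not move the
        # log-likelihood materially, otherwise the rule is too coarse
        alt = QuadratureConfig(2 * quadrature.n_nodes, quadrature.method)
        alt_ll = FourStateEngine(dataset, spec, alt).total_loglik(x)
        if abs(alt_ll - loglik) > 1e-6 * (1.0 + abs(loglik)):
            warnings.warn(
                f"quadrature not converged at the optimum: {loglik:.10f} vs "
                f"{alt_ll:.10f} with doubled nodes; increase n_quadrature",
                stacklevel=2,
            )

    H = fd_hessian(negll, x, cfg.hessian_step)
    cov = _invert_information(H)
    return FittedModel(
        spec=spec,
        params=spec.unflatten(x),
        x=x,
        param_names=spec.parameter_names,
        loglik=float(loglik),
        hessian=H,
        cov_naive=cov,
        converged=bool(res.success),
        n_patients=engine.n_patients,
        message=str(res.message),
        boundary_flags=_boundary_flags(spec, x),
    )


def symmetry_test(fitted: FittedModel) -> pd.DataFrame:
    """Wald tests of the contralateral symmetry offsets (gamma > 0).

    One row per offset with the estimate, 95% CI, z statistic and the
    one-sided p-value for H1: gamma > 0 (symmetric damage pattern).
    """
    if not fitted.spec.offset_names:
        raise SpecError("symmetry_test requires a model fitted with symmetry offsets")
    rows = []
    ci = fitted.conf_int()
    se = fitted.se()
    for name in fitted.spec.offset_names:
        i = fitted.param_names.index(name)
        z = fitted.x[i] / se[i] if se[i] > 0 else np.inf
        rows.append(
            {
                "offset": name,
                "estimate": fitted.x[i],
                "se": se[i],
                "ci_low": ci[i, 0],
                "ci_high": ci[i, 1],
                "z": z,
                "p_one_sided": float(norm.sf(z)),
            }
        )
    return pd.DataFrame(rows)


class FourStateFrailtyModel(BaseEstimator):
    """Four-state paired-damage model with shared gamma frailty.

    scikit-learn style estimator: ``fit(X)`` takes a long-format panel
    (:class:`PanelDataset` or equivalent DataFrame) and exposes fitted
    attributes with trailing underscores.  ``score(X)`` returns the mean
    per-patient marginal log-likelihood under the fitted parameters.

    Parameters
    ----------
    per_location_baselines : one pair of first-damage baselines per joint
        location (as in the symmetry analysis) instead of shared baselines.
    symmetry_offsets : express second-damage baselines as the same hand's
        first-damage baseline times ``exp(gamma)``.
    activity_design : attach the joint-activity covariate design.
    n_quadrature, quadrature_method : frailty integration rule.
    """

    def __init__(
        self,
        per_location_baselines: bool = False,
        symmetry_offsets: bool = True,
        activity_design: bool = False,
        frailty: bool = True,
        n_quadrature: int = 30,
        quadrature_method: str = "genlaguerre",
        gtol: float = 1e-5,
        maxiter: int = 500,
        cross_check_quadrature: bool = True,
    ):
        self.per_location_baselines = per_location_baselines
        self.symmetry_offsets = symmetry_offsets
        self.activity_design = activity_design
        self.frailty = frailty
        self.n_quadrature = n_quadrature
        self.quadrature_method = quadrature_method
        self.gtol = gtol
        self.maxiter = maxiter
        self.cross_check_quadrature = cross_check_quadrature

    def _as_dataset(self, X) -> PanelDataset:
        return X if isinstance(X, PanelDataset) else PanelDataset(X)

    def fit(self, X, y=None):
        ds = self._as_dataset(X)
        self.spec_ = build_four_state_spec(
            per_location_baselines=self.per_location_baselines,
            symmetry_offsets=self.symmetry_offsets,
            activity_design=self.activity_design,
            frailty=self.frailty,
        )
        self.result_ = fit_frailty_model(
            ds,
            self.spec_,
            optimizer_config=OptimizerConfig(
                gtol=self.gtol, maxiter=self.maxiter,
                cross_check_quadrature=self.cross_check_quadrature,
            ),
            quadrature=QuadratureConfig(self.n_quadrature, self.quadrature_method),
        )
        self.params_ = self.result_.params
        self.loglik_ = self.result_.loglik
        self.theta_ = self.result_.theta
        self.theta_ci_ = self.result_.theta_ci
        self.converged_ = self.result_.converged
        self.n_parameters_ = self.spec_.n_parameters
        if self.symmetry_offsets:
            self.symmetry_ = symmetry_test(self.result_)
        return self

    def score(self, X, y=None) -> float:
        ds = self._as_dataset(X)
        if any(e.role != "time-epoch" for e in self.spec_.covariate_design):
            ds, _ = ds.complete_case()
        engine = FourStateEngine(
            ds, self.spec_, QuadratureConfig(self.n_quadrature, self.quadrature_method)
        )
        return float(np.mean(engine.patient_loglik(self.result_.x)))

    def summary(self, robust: bool = False) -> pd.DataFrame:
        return self.result_.summary_table(robust)
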