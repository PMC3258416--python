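"""Fitted-model container shared by the frailty and working-independence fits."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import FitError
from .model_spec import ParameterSet, TransitionModelSpec


@dataclass
class FittedModel:
    """Estimates, curvature and derived inference for one model fit.

    ``hessian`` is the Hessian of the *negative* log-likelihood at the
    optimum (the observed information); ``cov_naive`` is its inverse and
    ``cov_robust``, when present, the information-sandwich covariance built
    from per-patient scores.  Intensity-ratio confidence intervals are the
    exponentials of the coefficient-scale interval endpoints; the frailty
    variance interval is computed on the log scale and exponentiated.
    """

    spec: TransitionModelSpec
    params: ParameterSet
    x: np.ndarray
    param_names: Tuple[str, ...]
    loglik: float
    hessian: np.ndarray
    cov_naive: np.ndarray
    cov_robust: Optional[np.ndarray] = None
    converged: bool = True
    n_patients: int = 0
    message: str = ""
    boundary_flags: List[str] = field(default_factory=list)
    scores: Optional[np.ndarray] = None  # per-patient score vectors (N, p)

    def _cov(self, robust: bool) -> np.ndarray:
        if robust:
            if self.cov_robust is None:
                raise FitError("no robust covariance available for this fit")
            return self.cov_robust
        return self.cov_naive

    def se(self, robust: bool = False) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self._cov(robust)), 0.0, None))

    def conf_int(self, robust: bool = False, level: float = 0.95) -> np.ndarray:
        z = norm.ppf(0.5 + level / 2)
        se = self.se(robust)
        return np.column_stack([self.x - z * se, self.x + z * se])

    # -- convenience views -------------------------------------------------

    def _kind(self, name: str) -> str:
        if name in self.spec.baseline_names:
            return "baseline"
        if name in self.spec.offset_names:
            return "offset"
        if name == "log_theta":
            return "frailty-variance"
        return "coefficient"

    def summary_table(self, robust: bool = False, level: float = 0.95) -> pd.DataFrame:
        """One row per free parameter with estimate, SE, CI and exp-scale CI.

        For baselines the exp columns are the intensity (1/year); for offsets
        and coefficients they are intensity ratios; for ``log_theta`` the
        frailty variance.
        """
        ci = self.conf_int(robust, level)
        df = pd.DataFrame(
            {
                "parameter": list(self.param_names),
                "kind": [self._kind(n) for n in self.param_names],
                "estimate": self.x,
                "se": self.se(robust),
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            }
        )
        df["exp_estimate"] = np.exp(df["estimate"])
        df["exp_low"] = np.exp(df["ci_low"])
        df["exp_high"] = np.exp(df["ci_high"])
        return df

    def intensity_ratio_table(self, robust: bool = False, level: float = 0.95) -> pd.DataFrame:
        """Intensity ratios (exp of coefficients and offsets) with CIs."""
        t = self.summary_table(robust, level)
        t = t[t["kind"].isin(["coefficient", "offset"])]
        return t[
            ["parameter", "kind", "estimate", "se", "ci_low", "ci_high",
             "exp_estimate", "exp_low", "exp_high"]
        ].rename(
            columns={
                "exp_estimate": "intensity_ratio",
                "exp_low": "ratio_low",
                "exp_high": "ratio_high",
            }
        ).reset_index(drop=True)

    @property
    def theta(self) -> Optional[float]:
        return self.params.theta

    @property
    def theta_ci(self) -> Optional[Tuple[float, float]]:
        if not self.spec.frailty:
            return None
        i = self.param_names.index("log_theta")
        lo, hi = self.conf_int()[i]
        return float(np.exp(lo)), float(np.exp(hi))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<FittedModel {self.spec.name!r}: loglik={self.loglik:.3f}, "
            f"{len(self.param_names)} parameters, converged={self.converged}>"
        )
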