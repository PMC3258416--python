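"""Vectorized panel-likelihood engines for the two hand-joint models.

Each engine precomputes, from a :class:`~jointmsm.panel_io.PanelDataset` and a
:class:`~jointmsm.model_spec.TransitionModelSpec`, flat interval arrays
(patient index, interval length, observed from/to states, covariate design
columns) and then evaluates log-likelihoods as pure array expressions using
the closed-form interval probabilities in :mod:`jointmsm._kernels`.  The
slower but fully general route via ``scipy.linalg.expm``
(:func:`jointmsm.ctmc.path_probability`) is used to cross-check these engines
in the test suite.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._kernels import phi, threestate_matrix, threestate_transient
from ._quadrature import QuadratureConfig, gamma_quadrature
from .exceptions import DataValidityError, SpecError
from .model_spec import TransitionModelSpec, joint_type
from .panel_io import PanelDataset, _joint_states, _paired_states

_TINY = 1e-300


def _crude_initial_vector(spec, from_s, to_s, dt) -> np.ndarray:
    """Initial parameter vector from location-pooled crude transition rates.

    Baselines start at the log crude rate (events / person-time in the origin
    state, with a half-event continuity correction), reparameterization
    offsets at the log ratio of crude rates, coefficients at zero and the log
    frailty variance at zero.
    """
    pos = {name: k for k, name in enumerate(spec.parameter_names)}
    rate = {}
    for (i, j) in spec.allowed_transitions:
        n_ev = float(np.sum((from_s == i) & (to_s == j))) + 0.5
        expo = float(np.sum(dt[from_s == i])) + 1e-6
        rate[(i, j)] = n_ev / expo
    x = np.zeros(spec.n_parameters)
    for (_loc, tr), bid in spec.baseline_sharing.items():
        x[pos[bid]] = np.log(rate[tr])
    for tr, (ref, oid) in spec.reparam_offsets.items():
        x[pos[oid]] = np.log(rate[tr] / rate[ref])
    return x


class FourStateEngine:
    """Marginal likelihood of the four-state paired-damage model.

    Supports shared or per-location baselines, contralateral symmetry
    offsets, the activity covariate design, and a gamma frailty shared by a
    patient's 14 joint-location processes (integrated out by quadrature).
    """

    _COVARIATES = (
        "act_L", "act_R", "tend_L", "tend_R",
        "eff_L", "eff_R", "ever_L", "ever_R",
    )

    def __init__(
        self,
        ds: PanelDataset,
        spec: TransitionModelSpec,
        quadrature: QuadratureConfig = QuadratureConfig(),
    ):
        if tuple(spec.states) != (1, 2, 3, 4):
            raise SpecError("FourStateEngine requires the four-state spec")
        self.spec = spec
        self.quadrature = quadrature
        pos = {name: k for k, name in enumerate(spec.parameter_names)}
        nb, no = len(spec.baseline_names), len(spec.offset_names)
        self._coef_slice = slice(nb + no, nb + no + len(spec.coef_names))

        wide = _paired_states(ds).sort_values(["patient_id", "location", "visit"])
        for side in "LR":
            to_col, ef_col = f"tender_only_{side}", f"effused_{side}"
            wide[f"act_{side}"] = (
                (wide[to_col] == 1) | (wide[ef_col] == 1)
            ).astype(float)
            wide[f"tend_{side}"] = (wide[to_col] == 1).astype(float)
            wide[f"eff_{side}"] = (wide[ef_col] == 1).astype(float)
            wide[f"ever_{side}"] = (
                wide.groupby(["patient_id", "location"])[f"act_{side}"].cummax()
            )
        needed = {e.covariate for e in spec.covariate_design}
        unknown = needed - set(self._COVARIATES)
        if unknown:
            raise SpecError(
                f"engine does not provide covariates {sorted(unknown)}; "
                "use ctmc.path_probability for custom designs"
            )
        if needed:
            act_cols = [f"{v}_{s}" for v in ("tender_only", "effused") for s in "LR"]
            if wide[act_cols].isna().any().any():
                raise DataValidityError(
                    "activity covariates contain missing values; apply "
                    "PanelDataset.complete_case() first"
                )

        grp = wide.groupby(["patient_id", "location"], sort=False)
        nxt_state = grp["state"].shift(-1).to_numpy()
        nxt_time = grp["time_L"].shift(-1).to_numpy()
        cur_state = wide["state"].to_numpy()
        keep = ~np.isnan(nxt_state) & (cur_state != 4)
        self.from_s = cur_state[keep].astype(np.int64)
        self.to_s = nxt_state[keep].astype(np.int64)
        self.dt = (nxt_time[keep] - wide["time_L"].to_numpy()[keep]).astype(float)

        patients = np.sort(ds.df["patient_id"].unique())
        self.patients = patients
        self.n_patients = len(patients)
        pid_map = {p: k for k, p in enumerate(patients)}
        self.pidx = wide["patient_id"].map(pid_map).to_numpy()[keep]

        locs = wide["location"].to_numpy()[keep]
        self._bcol: Dict[Tuple[int, int], np.ndarray] = {}
        self._opos: Dict[Tuple[int, int], Optional[int]] = {}
        for tr in spec.allowed_transitions:
            ids = {loc: pos[spec.baseline_id(loc, tr)] for loc in spec.locations}
            self._bcol[tr] = np.vectorize(ids.get)(locs) if len(locs) else np.zeros(0, int)
            self._opos[tr] = (
                pos[spec.reparam_offsets[tr][1]] if tr in spec.reparam_offsets else None
            )
        ncoef = len(spec.coef_names)
        cpos = {c: k for k, c in enumerate(spec.coef_names)}
        self._Z: Dict[Tuple[int, int], np.ndarray] = {}
        for tr in spec.allowed_transitions:
            Z = np.zeros((keep.sum(), ncoef))
            for eff in spec.covariate_design:
                if tr in eff.transitions:
                    Z[:, cpos[eff.coef_id]] += wide[eff.covariate].to_numpy()[keep]
            self._Z[tr] = Z

        self.groups = {}
        for f, t in zip(*np.unique(np.stack([self.from_s, self.to_s]), axis=1)):
            self.groups[(int(f), int(t))] = np.flatnonzero(
                (self.from_s == f) & (self.to_s == t)
            )

    # -- evaluation --------------------------------------------------------

    def _rates(self, x: np.ndarray):
        q = {}
        coefs = x[self._coef_slice]
        for tr in self.spec.allowed_transitions:
            lq = x[self._bcol[tr]]
            if self._opos[tr] is not None:
                lq = lq + x[self._opos[tr]]
            if coefs.size:
                lq = lq + self._Z[tr] @ coefs
            q[tr] = np.exp(np.clip(lq, -50.0, 50.0))
        return q

    def patient_loglik(self, x: np.ndarray) -> np.ndarray:
        """Vector of per-patient marginal log-likelihood contributions."""
        x = np.asarray(x, dtype=float)
        N = self.n_patients
        if self.dt.size == 0:
            return np.zeros(N)
        q = self._rates(x)
        q12, q13 = q[(1, 2)], q[(1, 3)]
        q24, q34 = q[(2, 4)], q[(3, 4)]
        a = q12 + q13
        r = np.zeros_like(self.dt)
        m1, m2, m3 = self.from_s == 1, self.from_s == 2, self.from_s == 3
        r[m1], r[m2], r[m3] = a[m1], q24[m2], q34[m3]
        E = np.bincount(self.pidx, weights=r * self.dt, minlength=N)

        if self.spec.frailty:
            theta = float(np.exp(np.clip(x[-1], -40.0, 40.0)))
            u, w = gamma_quadrature(
                theta, self.quadrature.n_nodes, self.quadrature.method
            )
        else:
            u, w = np.ones(1), np.ones(1)
        M = len(u)
        L = -np.outer(u, E)
        dt = self.dt
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            for (f, t), idx in self.groups.items():
                if f == t:
                    continue  # survival factor already in the exposure term
                if (f, t) == (1, 2) or (f, t) == (1, 3):
                    qft = q12 if t == 2 else q13
                    qexit = q24 if t == 2 else q34
                    X = (
                        np.log(qft[idx] * dt[idx])[None, :]
                        + np.log(u)[:, None]
                        + np.log(phi(np.outer(u, (a[idx] - qexit[idx]) * dt[idx])))
                    )
                elif (f, t) in ((2, 4), (3, 4)):
                    qe = q24 if f == 2 else q34
                    xx = np.outer(u, qe[idx] * dt[idx])
                    X = np.log(-np.expm1(-xx)) + xx
                elif (f, t) == (1, 4):
                    audt = np.outer(u, a[idx] * dt[idx])
                    p11 = np.exp(-audt)
                    p12 = np.outer(u, q12[idx] * dt[idx]) * p11 * phi(
                        np.outer(u, (a[idx] - q24[idx]) * dt[idx])
                    )
                    p13 = np.outer(u, q13[idx] * dt[idx]) * p11 * phi(
                        np.outer(u, (a[idx] - q34[idx]) * dt[idx])
                    )
                    p14 = np.clip(1.0 - p11 - p12 - p13, _TINY, 1.0)
                    X = np.log(p14) + audt
                else:  # pragma: no cover - excluded by panel validation
                    raise DataValidityError(f"impossible observed transition {f}->{t}")
                for m in range(M):
                    L[m] += np.bincount(self.pidx[idx], weights=X[m], minlength=N)
        with np.errstate(divide="ignore"):
            logw = np.log(w)
        return logsumexp(logw[:, None] + L, axis=0)

    def total_loglik(self, x: np.ndarray) -> float:
        return float(np.sum(self.patient_loglik(x)))

    def crude_initial_vector(self) -> np.ndarray:
        return _crude_initial_vector(self.spec, self.from_s, self.to_s, self.dt)


class ThreeStateEngine:
    """Working-independence likelihood of the 3-state activity-damage model.

    One process per hand joint (28 per patient); follow-up for a joint is
    truncated at its first visit with observed damage.  Piecewise-constant
    time epochs are handled either by assigning each interval the epoch of
    its left endpoint (default, consistent with covariate carry-forward) or
    by exact splitting at epoch boundaries (chained interval matrices).
    """

    def __init__(
        self,
        ds: PanelDataset,
        spec: TransitionModelSpec,
        exact_epoch_split: bool = False,
    ):
        if tuple(spec.states) != (1, 2, 3):
            raise SpecError("ThreeStateEngine requires the three-state spec")
        self.spec = spec
        self.exact_epoch_split = bool(exact_epoch_split)
        pos = {name: k for k, name in enumerate(spec.parameter_names)}
        nb, no = len(spec.baseline_names), len(spec.offset_names)
        self._coef_slice = slice(nb + no, nb + no + len(spec.coef_names))

        ds_cc, _ = ds.complete_case()
        js = _joint_states(ds_cc).copy()
        js = js.sort_values(["patient_id", "location", "side", "visit"])

        # covariates at each visit
        act = (js["state"] == 2).astype(float)
        js["_act"] = act
        js["ever_active"] = js.groupby(
            ["patient_id", "location", "side"], sort=False
        )["_act"].cummax()
        dmg = ds_cc.df.pivot_table(
            index=["patient_id", "location", "visit"], columns="side",
            values="damage", aggfunc="first",
        )
        key = pd.MultiIndex.from_frame(js[["patient_id", "location", "visit"]])
        opp_side = js["side"].map({"L": "R", "R": "L"})
        opp = np.where(
            opp_side.to_numpy() == "R",
            dmg["R"].reindex(key).to_numpy(),
            dmg["L"].reindex(key).to_numpy(),
        )
        js["opp_damage"] = np.nan_to_num(opp, nan=0.0)
        jt = js["location"].map(joint_type)
        for level in ("MCP", "PIP", "DIP", "MCP1", "PIP1"):
            js[f"jt_{level}"] = (jt == level).astype(float)

        grp = js.groupby(["patient_id", "location", "side"], sort=False)
        nxt_state = grp["state"].shift(-1).to_numpy()
        nxt_time = grp["time"].shift(-1).to_numpy()
        keep = ~np.isnan(nxt_state)
        self.from_s = js["state"].to_numpy()[keep].astype(np.int64)
        self.to_s = nxt_state[keep].astype(np.int64)
        t_left = js["time"].to_numpy()[keep].astype(float)
        self.t_left = t_left
        self.dt = (nxt_time[keep] - t_left).astype(float)
        if np.any(self.from_s == 3):  # pragma: no cover - removed by truncation
            raise DataValidityError("joint observed after damage")

        patients = np.sort(ds_cc.df["patient_id"].unique())
        self.patients = patients
        self.n_patients = len(patients)
        pid_map = {p: k for k, p in enumerate(patients)}
        self.pidx = js["patient_id"].map(pid_map).to_numpy()[keep]
        unit_key = (
            js["patient_id"].astype(str) + ":" + js["location"] + ":" + js["side"]
        )
        codes, uniques = pd.factorize(unit_key, sort=False)
        self.uidx = codes[keep]
        self.n_units = len(uniques)

        needed = {
            e.covariate for e in spec.covariate_design if e.role != "time-epoch"
        }
        known = {"ever_active", "opp_damage"} | {f"jt_{l}" for l in
                 ("MCP", "PIP", "DIP", "MCP1", "PIP1")}
        unknown = needed - known
        if unknown:
            raise SpecError(
                f"engine does not provide covariates {sorted(unknown)}; "
                "use ctmc.path_probability for custom designs"
            )
        ncoef = len(spec.coef_names)
        cpos = {c: k for k, c in enumerate(spec.coef_names)}
        self._bpos = {}
        self._opos = {}
        self._Z = {}
        n_int = int(keep.sum())
        for tr in spec.allowed_transitions:
            self._bpos[tr] = pos[spec.baseline_id(None, tr)]
            self._opos[tr] = (
                pos[spec.reparam_offsets[tr][1]] if tr in spec.reparam_offsets else None
            )
            Z = np.zeros((n_int, ncoef))
            for eff in spec.covariate_design:
                if eff.role == "time-epoch" or tr not in eff.transitions:
                    continue
                Z[:, cpos[eff.coef_id]] += js[eff.covariate].to_numpy()[keep]
            self._Z[tr] = Z

        # epoch machinery: parameter positions per (transition, epoch)
        n_epochs = len(spec.time_epochs) + 1
        self.n_epochs = n_epochs
        self._eppos = {}
        for tr in spec.allowed_transitions:
            idxs = np.full(n_epochs, -1, dtype=int)
            for eff in spec.covariate_design:
                if eff.role == "time-epoch" and tr in eff.transitions:
                    idxs[eff.epoch_index] = pos[eff.coef_id]
            self._eppos[tr] = idxs
        cuts = np.asarray(spec.time_epochs, dtype=float)
        if spec.time_epochs and not exact_epoch_split:
            self._epoch_left = np.searchsorted(cuts, t_left, side="right")
        elif spec.time_epochs:
            # overlap of each interval with each epoch [c_{e}, c_{e+1})
            edges = np.concatenate([[0.0], cuts, [np.inf]])
            lo = np.maximum(t_left[:, None], edges[None, :-1])
            hi = np.minimum((t_left + self.dt)[:, None], edges[None, 1:])
            self._seg_dt = np.clip(hi - lo, 0.0, None)
        else:
            self._epoch_left = np.zeros(n_int, dtype=int)

    def _epoch_values(self, x: np.ndarray, tr) -> np.ndarray:
        idxs = self._eppos[tr]
        return np.where(idxs >= 0, x[np.maximum(idxs, 0)], 0.0)

    def _base_log_rates(self, x: np.ndarray):
        coefs = x[self._coef_slice]
        lq = {}
        for tr in self.spec.allowed_transitions:
            v = np.full(self.dt.shape, x[self._bpos[tr]])
            if self._opos[tr] is not None:
                v = v + x[self._opos[tr]]
            if coefs.size:
                v = v + self._Z[tr] @ coefs
            lq[tr] = v
        return lq

    def _interval_logprob(self, x: np.ndarray) -> np.ndarray:
        lq = self._base_log_rates(x)
        trs = ((1, 2), (2, 1), (1, 3), (2, 3))
        if self.spec.time_epochs and self.exact_epoch_split:
            n_int = self.dt.size
            Ptot = np.broadcast_to(np.eye(3), (n_int, 3, 3)).copy()
            for e in range(self.n_epochs):
                qs = [
                    np.exp(np.clip(lq[tr] + self._epoch_values(x, tr)[e], -50.0, 50.0))
                    for tr in trs
                ]
                Pe = threestate_matrix(*qs, self._seg_dt[:, e])
                Ptot = Ptot @ Pe
            p = Ptot[np.arange(n_int), self.from_s - 1, self.to_s - 1]
            return np.log(np.maximum(p, _TINY))
        qs = []
        for tr in trs:
            v = lq[tr]
            if self.spec.time_epochs:
                v = v + self._epoch_values(x, tr)[self._epoch_left]
            qs.append(np.exp(np.clip(v, -50.0, 50.0)))
        p11, p12, p21, p22 = threestate_transient(*qs, self.dt)
        p13 = np.clip(1.0 - p11 - p12, 0.0, 1.0)
        p23 = np.clip(1.0 - p21 - p22, 0.0, 1.0)
        table = {(1, 1): p11, (1, 2): p12, (1, 3): p13,
                 (2, 1): p21, (2, 2): p22, (2, 3): p23}
        out = np.empty(self.dt.shape)
        for (f, t), p in table.items():
            mask = (self.from_s == f) & (self.to_s == t)
            if mask.any():
                out[mask] = np.log(np.maximum(p[mask], _TINY))
        return out

    def unit_loglik(self, x: np.ndarray) -> np.ndarray:
        """Per-joint log-likelihood contributions (working independence)."""
        if self.dt.size == 0:
            return np.zeros(self.n_units)
        return np.bincount(
            self.uidx, weights=self._interval_logprob(np.asarray(x, float)),
            minlength=self.n_units,
        )

    def patient_loglik(self, x: np.ndarray) -> np.ndarray:
        if self.dt.size == 0:
            return np.zeros(self.n_patients)
        return np.bincount(
            self.pidx, weights=self._interval_logprob(np.asarray(x, float)),
            minlength=self.n_patients,
        )

    def total_loglik(self, x: np.ndarray) -> float:
        if self.dt.size == 0:
            return 0.0
        return float(np.sum(self._interval_logprob(np.asarray(x, float))))

    def crude_initial_vector(self) -> np.ndarray:
        return _crude_initial_vector(self.spec, self.from_s, self.to_s, self.dt)

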