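"""Declarative multistate model structures for hand-joint damage processes.

A :class:`TransitionModelSpec` describes a continuous-time multistate model:
its state space, the transitions the model allows, how baseline transition
intensities are shared or reparameterized, and which covariates act on which
transitions (with equality constraints expressed by shared coefficient
identifiers).  The spec maps a flat unconstrained parameter vector onto
per-transition intensities, so optimizers never see the positivity
constraints: intensities and the frailty variance live on the log scale.

Two builders cover the models used for psoriatic-arthritis hand data:

* :func:`build_four_state_spec` — damage in a pair of contralateral joints
  (state 1 neither damaged, 2 right only, 3 left only, 4 both), irreversible,
  with optional contralateral-symmetry offsets ``gamma24``/``gamma34`` and an
  optional activity covariate design.
* :func:`build_three_state_spec` — per-joint activity/damage process
  (1 inactive, 2 active, 3 damaged; activity reversible, damage absorbing),
  with optional joint-type factor, ever-active and opposite-damage covariates,
  the ``lambda23 = lambda13 * exp(gamma)`` reparameterization, and
  piecewise-constant time epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .exceptions import MissingCovariateError, SpecError

Transition = Tuple[int, int]

#: The 14 hand joint locations (per hand).  MCP = metacarpophalangeal,
#: PIP = proximal interphalangeal, DIP = distal interphalangeal; digit 1 is
#: the thumb, which has no DIP joint.
JOINT_LOCATIONS: Tuple[str, ...] = (
    "MCP1", "MCP2", "MCP3", "MCP4", "MCP5",
    "PIP1", "PIP2", "PIP3", "PIP4", "PIP5",
    "DIP2", "DIP3", "DIP4", "DIP5",
)

#: Five-level joint-type factor: finger MCP/PIP/DIP plus the two thumb joints.
JOINT_TYPE_LEVELS: Tuple[str, ...] = ("MCP", "PIP", "DIP", "MCP1", "PIP1")


def joint_type(location: str) -> str:
    """Map a joint location label to its joint-type factor level."""
    if location not in JOINT_LOCATIONS:
        raise SpecError(f"unknown joint location {location!r}")
    if location in ("MCP1", "PIP1"):
        return location
    return location[:3]


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate acting on one or more transitions through one coefficient.

    Equality constraints are expressed by re-using a ``coef_id`` across
    several :class:`CovariateEffect` entries: all of them then move with a
    single free parameter.  Transitions not named in any entry for a given
    covariate implicitly carry coefficient 0.
    """

    covariate: str
    transitions: Tuple[Transition, ...]
    coef_id: str
    role: str = "generic"
    #: for role="time-epoch": which epoch (1-based; epoch 0 is the reference)
    epoch_index: Optional[int] = None


@dataclass
class ParameterSet:
    """Free parameters of a spec, on the unconstrained scale.

    ``log_baselines`` hold log baseline intensities (one per baseline
    identifier), ``offsets`` the reparameterization offsets (gamma, real
    scale), ``coefs`` the regression coefficients, and ``log_theta`` the log
    frailty variance (``None`` for frailty-free models).
    """

    log_baselines: dict
    offsets: dict = field(default_factory=dict)
    coefs: dict = field(default_factory=dict)
    log_theta: Optional[float] = None

    @property
    def theta(self) -> Optional[float]:
        return None if self.log_theta is None else float(np.exp(self.log_theta))


class TransitionModelSpec:
    """State space, allowed transitions and parameter structure of a model.

    Parameters
    ----------
    states : ordered state identifiers (integers, 1-based).
    allowed_transitions : ordered (from, to) pairs.
    absorbing_states : states with no outgoing transitions.
    baseline_sharing : mapping ``(location | None, transition) -> baseline id``.
        A ``None`` location means the baseline is shared across locations.
    reparam_offsets : mapping ``transition -> (reference transition, offset id)``;
        the transition's baseline is the reference transition's baseline (at
        the same location) times ``exp(offset)``.
    covariate_design : sequence of :class:`CovariateEffect`.
    frailty : whether the model carries a gamma frailty variance ``theta``.
    locations : joint location labels the model applies to.
    time_epochs : strictly increasing cut times (years, > 0) for
        piecewise-constant epoch effects; empty for homogeneous models.
    """

    def __init__(
        self,
        states: Sequence[int],
        allowed_transitions: Sequence[Transition],
        absorbing_states: Sequence[int],
        baseline_sharing: Mapping,
        reparam_offsets: Optional[Mapping] = None,
        covariate_design: Sequence[CovariateEffect] = (),
        frailty: bool = False,
        locations: Sequence[str] = JOINT_LOCATIONS,
        time_epochs: Sequence[float] = (),
        name: str = "multistate",
    ):
        self.states = tuple(states)
        self.allowed_transitions = tuple(tuple(t) for t in allowed_transitions)
        self.absorbing_states = tuple(absorbing_states)
        self.baseline_sharing = {
            (loc, tuple(tr)): bid for (loc, tr), bid in dict(baseline_sharing).items()
        }
        self.reparam_offsets = {
            tuple(tr): (tuple(ref), oid)
            for tr, (ref, oid) in dict(reparam_offsets or {}).items()
        }
        self.covariate_design = tuple(covariate_design)
        self.frailty = bool(frailty)
        self.locations = tuple(locations)
        self.time_epochs = tuple(float(c) for c in time_epochs)
        self.name = name
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        state_set = set(self.states)
        for (i, j) in self.allowed_transitions:
            if i not in state_set or j not in state_set:
                raise SpecError(f"transition {(i, j)} uses unknown states")
            if i == j:
                raise SpecError("self-transitions are not allowed")
        for s in self.absorbing_states:
            out = [t for t in self.allowed_transitions if t[0] == s]
            if out:
                raise SpecError(f"absorbing state {s} has outgoing transitions {out}")
        for tr, (ref, _oid) in self.reparam_offsets.items():
            if tr not in self.allowed_transitions:
                raise SpecError(f"reparam offset on disallowed transition {tr}")
            if ref not in self.allowed_transitions:
                raise SpecError(f"reparam reference {ref} is not an allowed transition")
        for tr in self.allowed_transitions:
            self.baseline_id(self.locations[0], tr)  # raises if unresolvable
        for eff in self.covariate_design:
            for tr in eff.transitions:
                if tuple(tr) not in self.allowed_transitions:
                    raise SpecError(
                        f"covariate {eff.covariate!r} acts on disallowed transition {tr}"
                    )
        if self.time_epochs:
            cuts = self.time_epochs
            if cuts[0] <= 0 or any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise SpecError("epoch cut times must be strictly increasing and > 0")

    def baseline_id(self, location: Optional[str], transition: Transition) -> str:
        """Resolve the baseline identifier for a transition at a location.

        Reparameterized transitions resolve to their *reference* transition's
        baseline identifier (the offset is applied separately).
        """
        transition = tuple(transition)
        if transition in self.reparam_offsets:
            transition = self.reparam_offsets[tuple(transition)][0]
        for key in ((location, transition), (None, transition)):
            if key in self.baseline_sharing:
                return self.baseline_sharing[key]
        raise SpecError(
            f"transition {transition} at location {location!r} has no baseline parameter"
        )

    # -- parameter vector layout ------------------------------------------

    @property
    def baseline_names(self) -> Tuple[str, ...]:
        seen = dict.fromkeys(self.baseline_sharing.values())
        return tuple(seen)

    @property
    def offset_names(self) -> Tuple[str, ...]:
        seen = dict.fromkeys(oid for _, oid in self.reparam_offsets.values())
        return tuple(seen)

    @property
    def coef_names(self) -> Tuple[str, ...]:
        seen = dict.fromkeys(e.coef_id for e in self.covariate_design)
        return tuple(seen)

    @property
    def parameter_names(self) -> Tuple[str, ...]:
        names = self.baseline_names + self.offset_names + self.coef_names
        if self.frailty:
            names = names + ("log_theta",)
        return names

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def flatten(self, params: ParameterSet) -> np.ndarray:
        """Pack a :class:`ParameterSet` into the flat unconstrained vector."""
        vec = [params.log_baselines[b] for b in self.baseline_names]
        vec += [params.offsets[o] for o in self.offset_names]
        vec += [params.coefs[c] for c in self.coef_names]
        if self.frailty:
            if params.log_theta is None:
                raise SpecError("frailty model requires log_theta")
            vec.append(params.log_theta)
        return np.asarray(vec, dtype=float)

    def unflatten(self, vec: np.ndarray) -> ParameterSet:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_parameters,):
            raise SpecError(
                f"parameter vector has shape {vec.shape}, expected ({self.n_parameters},)"
            )
        nb, no = len(self.baseline_names), len(self.offset_names)
        nc = len(self.coef_names)
        return ParameterSet(
            log_baselines=dict(zip(self.baseline_names, vec[:nb])),
            offsets=dict(zip(self.offset_names, vec[nb:nb + no])),
            coefs=dict(zip(self.coef_names, vec[nb + no:nb + no + nc])),
            log_theta=float(vec[-1]) if self.frailty else None,
        )

    # -- epochs ------------------------------------------------------------

    def epoch_index(self, t: float) -> int:
        """0-based epoch of time ``t`` given the spec's cut points."""
        return int(np.searchsorted(np.asarray(self.time_epochs), t, side="right"))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "states": list(self.states),
            "allowed_transitions": [list(t) for t in self.allowed_transitions],
            "absorbing_states": list(self.absorbing_states),
            "baseline_sharing": [
                {"location": loc, "transition": list(tr), "id": bid}
                for (loc, tr), bid in self.baseline_sharing.items()
            ],
            "reparam_offsets": [
                {"transition": list(tr), "reference": list(ref), "id": oid}
                for tr, (ref, oid) in self.reparam_offsets.items()
            ],
            "covariate_design": [
                {
                    "covariate": e.covariate,
                    "transitions": [list(t) for t in e.transitions],
                    "coef_id": e.coef_id,
                    "role": e.role,
                    "epoch_index": e.epoch_index,
                }
                for e in self.covariate_design
            ],
            "frailty": self.frailty,
            "locations": list(self.locations),
            "time_epochs": list(self.time_epochs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModelSpec":
        return cls(
            states=d["states"],
            allowed_transitions=[tuple(t) for t in d["allowed_transitions"]],
            absorbing_states=d["absorbing_states"],
            baseline_sharing={
                (b["location"], tuple(b["transition"])): b["id"]
                for b in d["baseline_sharing"]
            },
            reparam_offsets={
                tuple(r["transition"]): (tuple(r["reference"]), r["id"])
                for r in d.get("reparam_offsets", [])
            },
            covariate_design=[
                CovariateEffect(
                    covariate=e["covariate"],
                    transitions=tuple(tuple(t) for t in e["transitions"]),
                    coef_id=e["coef_id"],
                    role=e.get("role", "generic"),
                    epoch_index=e.get("epoch_index"),
                )
                for e in d.get("covariate_design", [])
            ],
            frailty=d.get("frailty", False),
            locations=d.get("locations", JOINT_LOCATIONS),
            time_epochs=d.get("time_epochs", ()),
            name=d.get("name", "multistate"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TransitionModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TransitionModelSpec":
        return cls.from_dict(json.loads(s))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<TransitionModelSpec {self.name!r}: {len(self.states)} states, "
            f"{len(self.allowed_transitions)} transitions, "
            f"{self.n_parameters} free parameters>"
        )


# ---------------------------------------------------------------------------
# builders


def build_four_state_spec(
    per_location_baselines: bool = False,
    symmetry_offsets: bool = False,
    activity_design: bool = False,
    frailty: bool = True,
) -> TransitionModelSpec:
    """Four-state paired-damage model for one joint location in both hands.

    States: 1 neither damaged, 2 right damaged, 3 left damaged, 4 both.
    Allowed transitions 1->2, 1->3, 2->4, 3->4; damage is irreversible and
    simultaneous bilateral damage (1->4) is structurally excluded so the
    left/right subprocesses compose.

    ``symmetry_offsets`` expresses the second-damage baselines in terms of the
    first-damage baselines of the same hand,
    ``lambda024 = lambda013 * exp(gamma24)`` and
    ``lambda034 = lambda012 * exp(gamma34)``: positive offsets mean a joint's
    damage rate rises once its contralateral partner is damaged (the
    rheumatological symmetry hypothesis).

    ``activity_design`` attaches the joint-activity covariates with their
    equality constraints: current opposite-joint activity (one shared
    coefficient ``alpha_opp1``), current transitive-joint tenderness/effusion
    out of state 1 (``tau_trans1``/``eps_trans1``) and into state 4
    (``tau_trans4``/``eps_trans4``), plus ever-active indicators
    (``rho_trans1``, ``rho_opp1``, ``rho_trans4``; past activity of the
    already-damaged joint has no effect on transitions into state 4).
    """
    allowed = ((1, 2), (1, 3), (2, 4), (3, 4))
    sharing: dict = {}
    locs: Iterable[Optional[str]] = JOINT_LOCATIONS if per_location_baselines else (None,)
    for loc in locs:
        tag = f"[{loc}]" if loc is not None else ""
        sharing[(loc, (1, 2))] = f"lambda12{tag}"
        sharing[(loc, (1, 3))] = f"lambda13{tag}"
        if not symmetry_offsets:
            sharing[(loc, (2, 4))] = f"lambda24{tag}"
            sharing[(loc, (3, 4))] = f"lambda34{tag}"
    reparam = {}
    if symmetry_offsets:
        # second damage of the LEFT joint (2->4) vs its first damage (1->3);
        # second damage of the RIGHT joint (3->4) vs its first damage (1->2)
        reparam = {(2, 4): ((1, 3), "gamma24"), (3, 4): ((1, 2), "gamma34")}

    design: list = []
    if activity_design:
        def eff(cov, tr, cid, role):
            design.append(CovariateEffect(cov, (tr,), cid, role))

        # out of state 1: transition 1->2 damages the right joint,
        # 1->3 the left joint (the "transitive" joint of the transition)
        eff("act_L", (1, 2), "alpha_opp1", "opposite-activity")
        eff("act_R", (1, 3), "alpha_opp1", "opposite-activity")
        eff("tend_R", (1, 2), "tau_trans1", "current-tender")
        eff("tend_L", (1, 3), "tau_trans1", "current-tender")
        eff("eff_R", (1, 2), "eps_trans1", "current-effused")
        eff("eff_L", (1, 3), "eps_trans1", "current-effused")
        eff("ever_R", (1, 2), "rho_trans1", "ever-active")
        eff("ever_L", (1, 3), "rho_trans1", "ever-active")
        eff("ever_L", (1, 2), "rho_opp1", "ever-active")
        eff("ever_R", (1, 3), "rho_opp1", "ever-active")
        # into state 4: 2->4 damages the left joint, 3->4 the right joint;
        # opposite-joint activity is omitted (dominant symmetry effect), and
        # rho_L34 = rho_R24 = 0 (no ever-active term for the damaged joint)
        eff("tend_L", (2, 4), "tau_trans4", "current-tender")
        eff("tend_R", (3, 4), "tau_trans4", "current-tender")
        eff("eff_L", (2, 4), "eps_trans4", "current-effused")
        eff("eff_R", (3, 4), "eps_trans4", "current-effused")
        eff("ever_L", (2, 4), "rho_trans4", "ever-active")
        eff("ever_R", (3, 4), "rho_trans4", "ever-active")

    return TransitionModelSpec(
        states=(1, 2, 3, 4),
        allowed_transitions=allowed,
        absorbing_states=(4,),
        baseline_sharing=sharing,
        reparam_offsets=reparam,
        covariate_design=design,
        frailty=frailty,
        name="four-state-paired-damage",
    )


def build_three_state_spec(
    joint_type_factor: bool = False,
    ever_active: bool = False,
    opposite_damage: bool = False,
    gamma_reparam: bool = False,
    time_epochs: Optional[Sequence[float]] = None,
    epoch_transitions: Optional[Sequence[Transition]] = None,
    joint_type_reference: str = "MCP",
    frailty: bool = False,
) -> TransitionModelSpec:
    """Three-state activity-damage model for a single hand joint.

    States: 1 no damage & inactive, 2 no damage & active, 3 damaged
    (absorbing).  Transitions 1<->2 (activity reversible), 1->3 and 2->3.

    ``gamma_reparam`` sets ``lambda023 = lambda013 * exp(gamma)``, so ``gamma``
    is the log intensity ratio of damage from the active vs the inactive
    state.  The joint-type factor (reference level configurable) and the
    ever-active indicator act on transitions out of state 1 only; the
    opposite-damage indicator acts on all four transitions.

    ``time_epochs`` adds piecewise-constant epoch indicator covariates
    (reference epoch ``[0, c1)``) on ``epoch_transitions`` (default: all).
    """
    allowed = ((1, 2), (2, 1), (1, 3), (2, 3))
    sharing = {
        (None, (1, 2)): "lambda12",
        (None, (2, 1)): "lambda21",
        (None, (1, 3)): "lambda13",
    }
    reparam = {}
    if gamma_reparam:
        reparam[(2, 3)] = ((1, 3), "gamma")
    else:
        sharing[(None, (2, 3))] = "lambda23"

    design: list = []
    if joint_type_factor:
        if joint_type_reference not in JOINT_TYPE_LEVELS:
            raise SpecError(
                f"unknown joint-type reference level {joint_type_reference!r}; "
                f"choose one of {JOINT_TYPE_LEVELS}"
            )
        for level in JOINT_TYPE_LEVELS:
            if level == joint_type_reference:
                continue
            for tr in ((1, 2), (1, 3)):
                design.append(
                    CovariateEffect(
                        f"jt_{level}", (tr,), f"jt_{level}:{tr[0]}{tr[1]}", "joint-type"
                    )
                )
    if ever_active:
        design.append(CovariateEffect("ever_active", ((1, 2),), "ever:12", "ever-active"))
        design.append(CovariateEffect("ever_active", ((1, 3),), "ever:13", "ever-active"))
    if opposite_damage:
        for tr in allowed:
            design.append(
                CovariateEffect(
                    "opp_damage", (tr,), f"opp:{tr[0]}{tr[1]}", "opposite-damage"
                )
            )
    cuts = tuple(time_epochs or ())
    if cuts:
        chosen = tuple(tuple(t) for t in (epoch_transitions or allowed))
        for e in range(1, len(cuts) + 1):
            for tr in chosen:
                design.append(
                    CovariateEffect(
                        f"epoch{e}", (tr,), f"epoch{e}:{tr[0]}{tr[1]}",
                        "time-epoch", epoch_index=e,
                    )
                )

    return TransitionModelSpec(
        states=(1, 2, 3),
        allowed_transitions=allowed,
        absorbing_states=(3,),
        baseline_sharing=sharing,
        reparam_offsets=reparam,
        covariate_design=design,
        frailty=frailty,
        time_epochs=cuts,
        name="three-state-activity-damage",
    )


# ---------------------------------------------------------------------------
# resolution


def resolve_parameters(
    spec: TransitionModelSpec,
    params: ParameterSet,
    joint_location: Optional[str] = None,
    covariates: Optional[Mapping[str, float]] = None,
    epoch_time: float = 0.0,
) -> dict:
    """Per-transition intensities ``lambda_ij = lambda0_ij * exp(beta'z)``.

    The frailty is *not* applied here (see :func:`jointmsm.ctmc.intensity_matrix`).
    Epoch indicator covariates are derived from ``epoch_time`` and need not be
    supplied in ``covariates``.  A covariate named in the design but missing
    from ``covariates`` raises :class:`MissingCovariateError` naming it.
    """
    covariates = dict(covariates or {})
    epoch = spec.epoch_index(epoch_time) if spec.time_epochs else 0
    out = {}
    for tr in spec.allowed_transitions:
        lp = params.log_baselines[spec.baseline_id(joint_location, tr)]
        if tr in spec.reparam_offsets:
            lp += params.offsets[spec.reparam_offsets[tr][1]]
        for effd in spec.covariate_design:
            if tr not in effd.transitions:
                continue
            if effd.role == "time-epoch":
                z = 1.0 if epoch == effd.epoch_index else 0.0
            elif effd.covariate in covariates:
                z = float(covariates[effd.covariate])
            else:
                raise MissingCovariateError(effd.covariate)
            lp += params.coefs[effd.coef_id] * z
        out[tr] = float(np.exp(lp))
    return out


def default_parameters(
    spec: TransitionModelSpec,
    log_baseline: float = np.log(0.01),
    log_theta: float = 0.0,
) -> ParameterSet:
    """A ParameterSet with every baseline at ``log_baseline`` and zeros elsewhere."""
    return ParameterSet(
        log_baselines={b: float(log_baseline) for b in spec.baseline_names},
        offsets={o: 0.0 for o in spec.offset_names},
        coefs={c: 0.0 for c in spec.coef_names},
        log_theta=float(log_theta) if spec.frailty else None,
    )
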