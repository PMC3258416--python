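"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

import jointmsm as jm


@pytest.fixture(scope="session")
def small_cohort():
    """A small, eventful cohort with frailty (used for engine/IO checks)."""
    cfg = jm.SimulationConfig(
        n_patients=30,
        theta=1.0,
        seed=42,
        damage=jm.DamageRates(lambda12=0.05, lambda13=0.05, gamma24=1.0, gamma34=1.0),
        visits=jm.VisitSchedule(
            gap_median=0.8, gap_sigma=0.4, geometric_p=0.3, min_visits=3, max_visits=9
        ),
    )
    return jm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def activity_cohort():
    """Cohort with active joints driving damage (for three-state checks)."""
    cfg = jm.SimulationConfig(
        n_patients=25,
        theta=0.0,
        seed=7,
        damage=jm.DamageRates(
            lambda12=0.02, lambda13=0.02, gamma24=0.0, gamma34=0.0,
            tau_trans1=2.0, eps_trans1=2.0, tau_trans4=2.0, eps_trans4=2.0,
        ),
        activity=jm.ActivityRates(onset=0.8, resolve=1.5, tender_to_effused=0.0),
        covariate_mode="continuous-hazard",
        visits=jm.VisitSchedule(
            gap_median=0.5, gap_sigma=0.3, geometric_p=0.4, min_visits=4, max_visits=8
        ),
    )
    return jm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def activity_panel(activity_cohort):
    return activity_cohort[0]


def four_state_params(l12=0.0028, l13=0.0027, l24=0.0215, l34=0.0234, theta=None):
    """ParameterSet for the shared-baseline four-state spec."""
    return jm.ParameterSet(
        log_baselines={
            "lambda12": np.log(l12), "lambda13": np.log(l13),
            "lambda24": np.log(l24), "lambda34": np.log(l34),
        },
        log_theta=None if theta is None else np.log(theta),
    )
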