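"""Gamma frailty: density, marginal likelihood, quadrature, model fitting."""

import numpy as np
import pytest
from scipy import integrate

import jointmsm as jm
from jointmsm import QuadratureConfig, gamma_quadrature
from jointmsm._likelihood import FourStateEngine
from jointmsm._numdiff import fd_gradient
from jointmsm.ctmc import PanelPath
from jointmsm.exceptions import SpecError
from jointmsm.frailty import fit_frailty_model, symmetry_test

from conftest import four_state_params


class TestFrailtyDensity:
    def test_theta_one_is_unit_exponential(self):
        assert jm.frailty_density(0.5, 1.0) == pytest.approx(np.exp(-0.5), abs=1e-12)

    @pytest.mark.parametrize("theta", [0.05, 0.5, 1.0, 3.81])
    def test_normalization_and_unit_mean(self, theta):
        total, _ = integrate.quad(lambda u: jm.frailty_density(u, theta), 0, np.inf)
        mean, _ = integrate.quad(lambda u: u * jm.frailty_density(u, theta), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)
        assert mean == pytest.approx(1.0, abs=1e-8)

    def test_small_theta_concentrates_at_one(self):
        lo, _ = integrate.quad(lambda u: jm.frailty_density(u, 0.01), 1e-12, 0.5)
        hi, _ = integrate.quad(lambda u: jm.frailty_density(u, 0.01), 1.5, np.inf)
        assert lo + hi < 1e-4

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            jm.frailty_density(0.5, -1.0)
        with pytest.raises(ValueError):
            jm.frailty_density(-0.5, 1.0)

    def test_distribution_object(self):
        fd = jm.FrailtyDistribution(2.0)
        assert fd.shape == fd.rate == 0.5
        assert fd.mean == 1.0 and fd.variance == 2.0


class TestGammaQuadrature:
    @pytest.mark.parametrize("theta", [0.05, 0.5, 2.0, 3.81])
    def test_laplace_transform_converges(self, theta):
        # E[e^{-cU}] = (1 + theta c)^{-1/theta}; the rule is near-exact at 30
        # nodes for moderate theta*c and refines cleanly for larger products
        for c in (0.1, 0.5, 2.0):
            exact = (1 + theta * c) ** (-1 / theta)
            u, w = gamma_quadrature(theta, 30)
            assert np.sum(w * np.exp(-c * u)) == pytest.approx(exact, abs=5e-7)
            u, w = gamma_quadrature(theta, 60)
            assert np.sum(w * np.exp(-c * u)) == pytest.approx(exact, abs=1e-9)

    def test_tiny_theta_fallback_is_stable(self):
        u, w = gamma_quadrature(1e-6, 30)
        assert np.all(np.isfinite(u)) and np.all(np.isfinite(w))
        assert np.sum(w * np.exp(-0.5 * u)) == pytest.approx(
            np.exp(-0.5), abs=1e-6
        )

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            gamma_quadrature(0.0, 30)


def _two_state_spec():
    """Single irreversible 1->2 process used for closed-form checks."""
    return jm.TransitionModelSpec(
        states=(1, 2), allowed_transitions=((1, 2),), absorbing_states=(2,),
        baseline_sharing={(None, (1, 2)): "lam"}, frailty=True,
    )


class TestMarginalLoglik:
    def test_two_state_closed_form(self):
        # marginal survival: (1 + theta*lambda*t)^{-1/theta} = 1/sqrt(2)
        spec = _two_state_spec()
        params = jm.ParameterSet(
            log_baselines={"lam": np.log(0.1)}, log_theta=np.log(2.0)
        )
        path = PanelPath(times=[0.0, 5.0], states=[1, 1])
        ll = jm.marginal_patient_loglik(spec, params, [path])
        assert np.exp(ll) == pytest.approx(0.7071068, abs=1e-7)
        assert np.exp(ll) == pytest.approx((1 + 2 * 0.1 * 5) ** (-0.5), abs=1e-8)

    def test_degenerate_frailty_limit(self):
        spec4 = jm.build_four_state_spec(frailty=True)
        params = four_state_params(0.05, 0.06, 0.3, 0.4, theta=1e-6)
        paths = [
            PanelPath(times=[0.0, 1.0, 2.0], states=[1, 1, 2]),
            PanelPath(times=[0.0, 1.0, 2.0], states=[1, 3, 4]),
        ]
        ll = jm.marginal_patient_loglik(spec4, params, paths)
        spec0 = jm.build_four_state_spec(frailty=False)
        params0 = four_state_params(0.05, 0.06, 0.3, 0.4)
        ll0 = sum(
            jm.path_probability(spec0, params0, p, return_log=True) for p in paths
        )
        assert ll == pytest.approx(ll0, abs=1e-4)

    def test_monte_carlo_oracle(self):
        spec4 = jm.build_four_state_spec(frailty=True)
        theta = 1.5
        params = four_state_params(0.2, 0.15, 0.5, 0.4, theta=theta)
        paths = [
            PanelPath(times=[0.0, 1.0, 3.0], states=[1, 2, 4]),
            PanelPath(times=[0.0, 1.0, 3.0], states=[1, 1, 3]),
        ]
        ll = jm.marginal_patient_loglik(spec4, params, paths)
        rng = np.random.default_rng(2024)
        n = 1_000_000
        u = rng.gamma(1 / theta, theta, n)
        # conditional joint path probability is cheap in closed form here
        spec0 = jm.build_four_state_spec(frailty=False)
        params0 = four_state_params(0.2, 0.15, 0.5, 0.4)
        base = [
            np.array(
                [jm.path_probability(spec0, params0, p, frailty_u=uu, return_log=True)
                 for p in paths]).sum()
            for uu in (1.0,)
        ]  # warm check that conditional evaluation works
        assert np.isfinite(base[0])
        from jointmsm._kernels import progressive4_logprob
        def joint_logp(uvec):
            out = np.zeros_like(uvec)
            for p in paths:
                for j in range(len(p.times) - 1):
                    dt = p.times[j + 1] - p.times[j]
                    out += progressive4_logprob(
                        0.2 * uvec, 0.15 * uvec, 0.5 * uvec, 0.4 * uvec,
                        dt, p.states[j], p.states[j + 1],
                    )
            return out
        vals = np.exp(joint_logp(u))
        mc, mc_se = vals.mean(), vals.std() / np.sqrt(n)
        assert abs(np.exp(ll) - mc) < 3 * mc_se

    def test_adaptive_mode_agrees(self):
        spec = _two_state_spec()
        params = jm.ParameterSet(
            log_baselines={"lam": np.log(0.1)}, log_theta=np.log(2.0)
        )
        path = PanelPath(times=[0.0, 5.0], states=[1, 1])
        ll_a = jm.marginal_patient_loglik(
            spec, params, [path], quadrature=QuadratureConfig(method="adaptive")
        )
        ll_q = jm.marginal_patient_loglik(spec, params, [path])
        assert ll_a == pytest.approx(ll_q, abs=1e-8)


class TestEngineAgreement:
    def test_vectorized_engine_matches_reference(self, small_cohort):
        panel, hist = small_cohort
        spec = jm.build_four_state_spec(symmetry_offsets=True, frailty=True)
        engine = FourStateEngine(panel, spec, QuadratureConfig(30))
        x = engine.crude_initial_vector()
        params = spec.unflatten(x)
        total_ref = 0.0
        for p in hist.patients:
            paths = []
            for loc, j in p.joints.items():
                states = [
                    1
                    + int(j.damage_R is not None and j.damage_R <= t)
                    + 2 * int(j.damage_L is not None and j.damage_L <= t)
                    for t in p.visit_times
                ]
                paths.append(PanelPath(p.visit_times, states))
            total_ref += jm.marginal_patient_loglik(
                spec, params, paths, quadrature=QuadratureConfig(30)
            )
        assert engine.total_loglik(x) == pytest.approx(total_ref, rel=1e-7)


class TestFitFrailtyModel:
    @pytest.fixture(scope="class")
    def fitted(self, small_cohort):
        panel, _ = small_cohort
        spec = jm.build_four_state_spec(symmetry_offsets=True, frailty=True)
        return panel, spec, fit_frailty_model(
            panel, spec, quadrature=QuadratureConfig(60)
        )

    def test_converged_with_small_gradient(self, fitted):
        panel, spec, fit = fitted
        assert fit.converged
        engine = FourStateEngine(panel, spec, QuadratureConfig(60))
        g = fd_gradient(lambda x: -engine.total_loglik(x), fit.x, 1e-5)
        assert np.max(np.abs(g)) < 1e-3  # independent finite-difference check

    def test_patient_relabeling_invariance(self, fitted, small_cohort):
        panel, spec, fit = fitted
        df = panel.df.copy()
        # reverse patient labels: a pure relabeling of the clusters
        relabel = {p: q for p, q in zip(sorted(df.patient_id.unique()),
                                        sorted(df.patient_id.unique())[::-1])}
        df["patient_id"] = df["patient_id"].map(relabel)
        fit2 = fit_frailty_model(
            jm.PanelDataset(df), spec, quadrature=QuadratureConfig(60)
        )
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)
        assert np.allclose(fit2.x, fit.x, atol=1e-4)

    def test_quadrature_refinement_at_optimum(self, fitted):
        panel, spec, fit = fitted
        ll_2x = FourStateEngine(
            panel, spec, QuadratureConfig(120)
        ).total_loglik(fit.x)
        assert abs(ll_2x - fit.loglik) < 1e-6 * (1 + abs(fit.loglik))

    def test_theta_interval_positive_and_ordered(self, fitted):
        _, _, fit = fitted
        lo, hi = fit.theta_ci
        assert 0 < lo < fit.theta < hi

    def test_summary_table_exponentiates_cis(self, fitted):
        _, _, fit = fitted
        t = fit.summary_table()
        assert np.allclose(t["exp_low"], np.exp(t["ci_low"]))
        assert (t["exp_low"] <= t["exp_high"]).all()


class TestSymmetryTest:
    def test_requires_offsets(self, small_panel):
        spec = jm.build_four_state_spec(symmetry_offsets=False, frailty=True)
        fit = fit_frailty_model(small_panel, spec, quadrature=QuadratureConfig(40))
        with pytest.raises(SpecError):
            symmetry_test(fit)

    def test_detects_symmetry_when_present(self, small_cohort):
        # generating offsets are gamma24 = gamma34 = 1 > 0
        panel, _ = small_cohort
        spec = jm.build_four_state_spec(symmetry_offsets=True, frailty=True)
        fit = fit_frailty_model(panel, spec, quadrature=QuadratureConfig(60))
        table = symmetry_test(fit)
        assert set(table["offset"]) == {"gamma24", "gamma34"}
        assert (table["p_one_sided"] < 0.05).all()

    def test_null_coverage_and_recovery(self):
        # gamma = 0 truth: CIs should cover 0 at roughly the nominal rate;
        # gamma24 = 1.5 truth: the estimate mean should be close to truth
        spec = jm.build_four_state_spec(symmetry_offsets=True, frailty=True)
        cover0 = 0
        reps = 30
        for r in range(reps):
            cfg = jm.SimulationConfig(
                n_patients=120, theta=1.0, seed=50_000 + r,
                damage=jm.DamageRates(lambda12=0.05, lambda13=0.05,
                                      gamma24=0.0, gamma34=0.0),
                visits=jm.VisitSchedule(gap_median=1.0, gap_sigma=0.3,
                                        geometric_p=0.5, min_visits=5, max_visits=5),
            )
            panel, _ = jm.simulate_cohort(cfg)
            fit = fit_frailty_model(panel, spec, quadrature=QuadratureConfig(40))
            i = fit.param_names.index("gamma24")
            lo, hi = fit.conf_int()[i]
            cover0 += lo <= 0.0 <= hi
        assert cover0 >= 25  # ~95% nominal with 30-replicate binomial noise

        ests = []
        for r in range(10):
            cfg = jm.SimulationConfig(
                n_patients=250, theta=1.0, seed=60_000 + r,
                damage=jm.DamageRates(lambda12=0.05, lambda13=0.05,
                                      gamma24=1.5, gamma34=1.5),
                visits=jm.VisitSchedule(gap_median=1.0, gap_sigma=0.3,
                                        geometric_p=0.5, min_visits=5, max_visits=5),
            )
            panel, _ = jm.simulate_cohort(cfg)
            fit = fit_frailty_model(panel, spec, quadrature=QuadratureConfig(40))
            ests.append(fit.x[fit.param_names.index("gamma24")])
        assert abs(np.mean(ests) - 1.5) < 0.15
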