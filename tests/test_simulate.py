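"""Cohort simulator: schedules, trajectories, closed-form and concordance checks."""

import numpy as np
import pytest
from scipy.stats import kstest

import jointmsm as jm


class TestVisitSchedules:
    def test_median_gap_and_visit_count(self):
        cfg = jm.SimulationConfig(n_patients=500, theta=0.0, seed=1,
                                  damage=jm.DamageRates(lambda12=0, lambda13=0))
        panel, hist = jm.simulate_cohort(cfg)
        s = jm.cohort_summaries(panel)
        assert abs(s["gap_median_years"] - 0.525) < 0.05
        assert abs(s["visits_median"] - 7) <= 1
        assert s["visits_min"] >= 2 and s["visits_max"] <= 47


class TestDegenerateConfigs:
    def test_zero_intensities_keep_everything_in_state_one(self):
        cfg = jm.SimulationConfig(
            n_patients=20, theta=1.0, seed=2,
            damage=jm.DamageRates(lambda12=0.0, lambda13=0.0),
            activity=jm.ActivityRates(onset=0.0),
        )
        panel, _ = jm.simulate_cohort(cfg)
        assert (panel.df["damage"] == 0).all()
        assert (panel.df["tender_only"] == 0).all()
        assert (panel.df["effused"] == 0).all()

    def test_zero_onset_never_active(self):
        rng = np.random.default_rng(3)
        path = jm.simulate_activity(jm.ActivityRates(onset=0.0), 100.0, rng)
        assert np.all(path.states == 0)

    def test_zero_escalation_never_effused(self):
        rng = np.random.default_rng(4)
        path = jm.simulate_activity(
            jm.ActivityRates(onset=1.0, resolve=1.0, tender_to_effused=0.0),
            500.0, rng,
        )
        assert np.all(path.states < 2)


class TestActivityProcess:
    def test_occupancy_matches_stationary_distribution(self):
        rates = jm.ActivityRates(onset=0.5, resolve=1.0,
                                 tender_to_effused=0.8, effused_to_tender=1.2)
        pi = np.array([
            1.0,
            rates.onset / rates.resolve,
            rates.onset * rates.tender_to_effused
            / (rates.resolve * rates.effused_to_tender),
        ])
        pi /= pi.sum()
        rng = np.random.default_rng(5)
        horizon = 10_000.0
        path = jm.simulate_activity(rates, horizon, rng)
        bounds = np.append(path.times, horizon)
        occ = np.zeros(3)
        for s, t0, t1 in zip(path.states, bounds[:-1], bounds[1:]):
            occ[s] += t1 - t0
        occ /= horizon
        assert np.max(np.abs(occ - pi)) < 0.02


class TestJointPairSimulation:
    def test_first_damage_times_exponential(self):
        # gamma = 0, no covariates: each side's damage time is exponential
        rng = np.random.default_rng(6)
        lam = 0.3
        d = jm.DamageRates(lambda12=lam, lambda13=lam, gamma24=0.0, gamma34=0.0)
        horizon = np.array([0.0, 60.0])
        act = jm.ActivityPath(np.array([0.0]), np.array([0]))
        times_R = []
        for _ in range(10_000):
            _, dmg_R = jm.simulate_joint_pair(1.0, d, act, act, horizon,
                                              "model-faithful", rng)
            if dmg_R is not None:
                times_R.append(dmg_R)
        # censoring at horizon=60 is negligible (P ~ e^-18)
        assert kstest(times_R, "expon", args=(0, 1 / lam)).pvalue > 0.01

    def test_contralateral_hazard_ratio_recovered(self):
        # gamma24 = gamma34 = log 4: post-contralateral-damage hazard ~ 4x
        rng = np.random.default_rng(7)
        lam, g = 0.15, np.log(4.0)
        d = jm.DamageRates(lambda12=lam, lambda13=lam, gamma24=g, gamma34=g)
        horizon = np.array([0.0, 8.0])
        act = jm.ActivityPath(np.array([0.0]), np.array([0]))
        first_events = 0
        first_exposure = 0.0
        second_events = 0
        second_exposure = 0.0
        for _ in range(10_000):
            dmg_L, dmg_R = jm.simulate_joint_pair(1.0, d, act, act, horizon,
                                                  "model-faithful", rng)
            t1 = min(x for x in (dmg_L, dmg_R, 8.0) if x is not None)
            both = dmg_L is not None and dmg_R is not None
            t2 = max(dmg_L or 0.0, dmg_R or 0.0) if both else 8.0
            # per-joint exposure before any damage (2 joints at risk)
            first_exposure += 2 * t1
            if dmg_L is not None or dmg_R is not None:
                first_events += 1
                second_exposure += t2 - t1
                second_events += both
        ratio = (second_events / second_exposure) / (first_events / first_exposure)
        assert abs(ratio - 4.0) / 4.0 < 0.15

    def test_event_times_distinct_within_pair(self, small_cohort):
        _, hist = small_cohort
        for p in hist.patients:
            for j in p.joints.values():
                times = j.event_times()
                assert len(times) == len(set(times))


class TestCoarsening:
    def test_visits_at_event_times_reconstruct_path(self):
        cfg = jm.SimulationConfig(
            n_patients=5, theta=1.0, seed=8,
            damage=jm.DamageRates(lambda12=0.1, lambda13=0.1),
            activity=jm.ActivityRates(onset=0.5),
        )
        _, hist = jm.simulate_cohort(cfg)
        p = hist.patients[0]
        event_times = sorted(
            {0.0, float(p.visit_times[-1])}
            | {t for j in p.joints.values() for t in j.event_times()
               if t <= p.visit_times[-1]}
        )
        panel = jm.coarsen_to_panel(
            jm.EventHistory(cfg, [p]), {p.patient_id: np.array(event_times)}
        )
        # at each recorded time the panel state equals the latent state
        # (times are compared on the unrounded schedule used for coarsening)
        for (_, loc, side), sub in panel.df.groupby(
            ["patient_id", "location", "side"]
        ):
            j = p.joints[loc]
            act = j.activity_L if side == "L" else j.activity_R
            dmg = j.damage_L if side == "L" else j.damage_R
            sub = sub.sort_values("visit")
            for (_, row), t in zip(sub.iterrows(), event_times):
                assert row["damage"] == int(dmg is not None and dmg <= t)
                s = act.state_at(t)
                assert row["tender_only"] == float(s == 1)
                assert row["effused"] == float(s == 2)

    def test_panel_damage_nondecreasing(self, small_panel):
        g = small_panel.df.groupby(["patient_id", "location", "side"])["damage"]
        assert (g.diff().dropna() >= 0).all()

    def test_apparent_one_to_four_frequency_matches_matrix_exponential(self):
        lam, g = 0.25, 1.0
        cfg = jm.SimulationConfig(
            n_patients=800, theta=0.0, seed=9,
            damage=jm.DamageRates(lambda12=lam, lambda13=lam, gamma24=g, gamma34=g),
            visits=jm.VisitSchedule(gap_median=1.0, gap_sigma=1e-9,
                                    geometric_p=0.9, min_visits=2, max_visits=2),
        )
        panel, _ = jm.simulate_cohort(cfg)
        table = jm.four_state_table(panel)
        spec = jm.build_four_state_spec(frailty=False)
        params = jm.ParameterSet(log_baselines={
            "lambda12": np.log(lam), "lambda13": np.log(lam),
            "lambda24": np.log(lam * np.e), "lambda34": np.log(lam * np.e)})
        P = jm.transition_probability(jm.intensity_matrix(spec, params), 1.0)
        n = table.counts[0].sum()
        freq = table.counts[0, 3] / n
        se = np.sqrt(P[0, 3] * (1 - P[0, 3]) / n)
        assert abs(freq - P[0, 3]) < 3 * se


class TestFrailtyAssociation:
    @staticmethod
    def _pair_concordance(panel):
        damaged = panel.df.groupby(
            ["patient_id", "location", "side"])["damage"].max()
        d = damaged.groupby("patient_id").sum().to_numpy()
        return d, float(np.sum(d * (d - 1) / 2))

    def test_frailty_increases_cross_joint_concordance(self):
        common = dict(
            n_patients=250,
            damage=jm.DamageRates(lambda12=0.03, lambda13=0.03,
                                  gamma24=0.0, gamma34=0.0),
            visits=jm.VisitSchedule(gap_median=1.0, gap_sigma=0.3,
                                    geometric_p=0.5, min_visits=4, max_visits=4),
        )
        panel0, _ = jm.simulate_cohort(jm.SimulationConfig(theta=0.0, seed=10, **common))
        panel2, _ = jm.simulate_cohort(jm.SimulationConfig(theta=2.0, seed=10, **common))
        d0, c0 = self._pair_concordance(panel0)
        d2, c2 = self._pair_concordance(panel2)
        assert c2 > c0
        # permutation test: reassigning damaged joints to patients at random
        # destroys the within-patient clustering of the theta=2 cohort
        rng = np.random.default_rng(11)
        total, n_pat = int(d2.sum()), len(d2)
        null = []
        for _ in range(500):
            counts = np.bincount(
                rng.integers(0, n_pat, total), minlength=n_pat
            )
            null.append(np.sum(counts * (counts - 1) / 2))
        p = (1 + np.sum(np.asarray(null) >= c2)) / 501
        assert p < 0.01


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_panels(self, tmp_path):
        cfg = jm.SimulationConfig(n_patients=15, theta=1.0, seed=123)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        jm.simulate_cohort(cfg)[0].write_csv(a)
        jm.simulate_cohort(cfg)[0].write_csv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seed_differs(self):
        cfg = jm.SimulationConfig(n_patients=15, theta=1.0, seed=123)
        p1, _ = jm.simulate_cohort(cfg)
        p2, _ = jm.simulate_cohort(cfg, seed=124)
        assert not p1.df.equals(p2.df)
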