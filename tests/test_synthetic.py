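"""Generator-level checks: determinism, randomization, marginal
distributions, censoring bookkeeping, and the PK simulation oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import kstest

from actrial.config import PopulationPK, TrialConfig, replace_config
from actrial.simulate import (block_randomize, simulate_ae_and_ecg_frames,
                              simulate_pk_profiles, simulate_survival_arrays,
                              simulate_trial, two_compartment_infusion)

LN2 = math.log(2)


class TestTrialGenerator:
    def test_block_randomization_arm_sizes(self, trial):
        sizes = trial.arm_sizes()
        assert sizes == {"experimental": 66, "control": 33}

    def test_partial_final_block(self):
        arms = block_randomize(100, (2, 1), np.random.default_rng(0))
        exp = (arms == "experimental").sum()
        assert exp in (66, 67) and len(arms) == 100

    def test_seed_determinism(self, default_config):
        a = simulate_trial(default_config, seed=7)
        b = simulate_trial(default_config, seed=7)
        for name in ("patients", "pk", "ae", "ecg", "ca199"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seeds_differ(self, default_config):
        a = simulate_trial(default_config, seed=1)
        b = simulate_trial(default_config, seed=2)
        assert not a.patients["os_time"].equals(b.patients["os_time"])

    def test_control_os_is_exponential(self):
        """KS test of uncensored control OS against Exp(ln2/median)."""
        cfg = TrialConfig(n_total=5000)
        rng = np.random.default_rng(99)
        is_exp, t, e, *_ = simulate_survival_arrays(cfg, rng,
                                                    full_followup=True)
        ctl = t[~is_exp]
        stat = kstest(ctl, "expon", args=(0, cfg.median_os_c / LN2))
        assert stat.pvalue > 0.01

    def test_large_sample_median_recovers_configured_median(self):
        cfg = TrialConfig(n_total=30000, median_os_c=7.0)
        rng = np.random.default_rng(5)
        is_exp, t, e, *_ = simulate_survival_arrays(cfg, rng,
                                                    full_followup=True)
        med = np.median(t[~is_exp])
        assert abs(med - 7.0) / 7.0 < 0.02

    def test_response_frequencies_converge(self):
        cfg = TrialConfig(n_total=20000)
        ds = simulate_trial(cfg, seed=3)
        for arm, probs in (("experimental", cfg.response_probs_e),
                           ("control", cfg.response_probs_c)):
            sub = ds.patients[ds.patients["arm"] == arm]
            freqs = sub["best_response"].value_counts(normalize=True)
            for cat, p in probs.items():
                assert abs(freqs.get(cat, 0.0) - p) < 0.02

    def test_censoring_bookkeeping(self, default_config, trial):
        p = trial.patients
        assert set(p["os_event"].unique()) <= {0, 1}
        cens = p[p["os_event"] == 0]
        cutoff = default_config.admin_cutoff
        # censored times never exceed the administrative window (columns are
        # stored rounded to 1e-4, hence the matching slack)
        assert (cens["os_time"] <= cutoff - cens["entry_month"] + 2e-4).all()

    def test_pfs_never_exceeds_os_on_event_pairs(self, trial):
        p = trial.patients
        both = p[(p["os_event"] == 1) & (p["pfs_event"] == 1)]
        assert (both["pfs_time"] <= both["os_time"] + 1e-12).all()

    def test_responders_shrink_by_week8(self, trial):
        p = trial.patients
        resp = p[p["best_response"].isin(["CR", "PR"])]
        assert (resp["week8_target_sum"] < resp["baseline_target_sum"]).all()

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(response_probs_e={"CR": 0.5, "PR": 0.4})


class TestPKGenerator:
    def test_zero_variability_matches_closed_form(self):
        pop = PopulationPK(iiv_cv={"cl": 0, "vc": 0, "vp": 0, "q": 0},
                           iov_cv=0.0)
        sim = simulate_pk_profiles(pop, 3, seed=1)
        ref = two_compartment_infusion(
            np.array(pop.sampling_times), pop.dose_ng,
            pop.infusion_duration_h, pop.cl_geomean, pop.vc_geomean,
            pop.vp_geomean, pop.q_geomean)
        ref[0] = 0.0  # pre-dose convention
        for _, grp in sim.samples.groupby(["patient_id", "day"]):
            got = grp.sort_values("time_h")["conc_ng_ml"].to_numpy()
            assert np.allclose(got, ref, rtol=1e-9)

    def test_closed_form_against_ode_integration(self):
        """The analytic two-compartment solution is checked against a direct
        numerical integration of the mass-balance ODEs."""
        dose, tinf = 230e6, 1.0
        cl, vc, vp, q = 7790.0, 50_000.0, 54_000.0, 15_000.0

        def rhs(t, y):
            a_c, a_p = y  # amounts in central / peripheral compartments
            rate_in = dose / tinf if t <= tinf else 0.0
            return [rate_in - (cl / vc) * a_c - (q / vc) * a_c + (q / vp) * a_p,
                    (q / vc) * a_c - (q / vp) * a_p]

        times = np.array([0.5, 1.0, 2.0, 4.0, 10.0, 25.0])
        sol = solve_ivp(rhs, (0, 25.0), [0.0, 0.0], t_eval=times,
                        rtol=1e-10, atol=1e-6, max_step=0.25)
        expected = sol.y[0] / vc
        got = two_compartment_infusion(times, dose, tinf, cl, vc, vp, q)
        assert np.allclose(got, expected, rtol=1e-6)

    def test_geometric_mean_cl_recovers_configured_truth(self):
        pop = PopulationPK()
        sim = simulate_pk_profiles(pop, 500, seed=11)
        gm = np.exp(np.log(sim.parameters["cl"]).mean())
        assert abs(gm - pop.cl_geomean) / pop.cl_geomean < 0.10

    def test_predose_sample_is_zero_and_concentrations_nonnegative(self):
        sim = simulate_pk_profiles(PopulationPK(), 20, seed=2)
        s = sim.samples
        assert (s.loc[s["time_h"] == 0.0, "conc_ng_ml"] == 0.0).all()
        assert (s["conc_ng_ml"] >= 0.0).all()

    def test_nonincreasing_sampling_times_rejected(self):
        with pytest.raises(ValueError):
            PopulationPK(sampling_times=(0.0, 2.0, 1.0))


class TestAEAndECGGenerator:
    def _patients(self, n_exp=65, n_ctrl=34):
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n_exp + n_ctrl)],
            "arm": ["experimental"] * n_exp + ["control"] * n_ctrl,
        })

    def test_zero_incidence_gives_no_records(self):
        ae, _ = simulate_ae_and_ecg_frames(
            self._patients(), {"nausea": (0.0, 0.0)}, seed=0)
        assert len(ae) == 0

    def test_certain_incidence_covers_arm(self):
        ae, _ = simulate_ae_and_ecg_frames(
            self._patients(), {"nausea": (1.0, 0.0)}, seed=0)
        assert ae["patient_id"].nunique() == 65
        assert set(ae["arm"]) == {"experimental"}

    def test_incidence_calibration_monte_carlo(self):
        """Mean nausea count over replicates ~= n * p (binomial mean)."""
        pats = self._patients()
        counts = []
        for rep in range(2000):
            ae, _ = simulate_ae_and_ecg_frames(
                pats, {"nausea": (0.338, 0.0)},
                rng=np.random.default_rng([17, rep]))
            counts.append(ae["patient_id"].nunique())
        expected = 65 * 0.338   # 21.97
        se = math.sqrt(65 * 0.338 * 0.662 / 2000)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_invalid_incidence_rejected(self):
        with pytest.raises(ValueError):
            simulate_ae_and_ecg_frames(self._patients(),
                                       {"nausea": (1.2, 0.0)}, seed=0)

    def test_qtc_fractions_respected_at_extremes(self):
        _, ecg = simulate_ae_and_ecg_frames(
            self._patients(), {}, seed=0, frac_qtc_30_60=1.0)
        from actrial.safety import qtcf_change_categories
        table, _ = qtcf_change_categories(ecg)
        assert (table["category"] == "(30,60]").all()
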