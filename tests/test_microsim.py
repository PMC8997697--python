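import copy

import numpy as np
import pytest

from deprescribe import ARM_REDUCTION, ARM_USUAL, PatientProfile, run_arm, simulate_patient
from deprescribe import risk_engine as re_
from deprescribe.microsim import run_base_case
from tests.conftest import make_flat_lifetable, uniform_cohort, zero_hazard_params


def make_patient(**kw):
    base = dict(
        age=84.0, sex="M", n_prior_cvd=0, ten_year_cvd_risk=0.0,
        baseline_utility=0.769, frailty="fit", n_drugs=2, maintained_reduction=True,
    )
    base.update(kw)
    return PatientProfile(**base)


class TestSimulatePatient:
    def test_zero_hazards_survives_all_cycles_event_free(self, base_params):
        p = zero_hazard_params(base_params, qx=0.0)
        traj = simulate_patient(make_patient(), ARM_USUAL, p, np.random.default_rng(0))
        assert len(traj.records) == 80
        assert all(r.state == "event-free" for r in traj.records)
        assert all(r.event is None for r in traj.records)

    def test_certain_death_first_cycle(self, base_params):
        p = zero_hazard_params(base_params, qx=1.0)
        traj = simulate_patient(make_patient(), ARM_USUAL, p, np.random.default_rng(0))
        assert len(traj.records) == 1
        assert traj.records[0].state == "dead"
        assert traj.records[0].event == "death"

    def test_increments_zero_after_death(self, base_params):
        p = copy.deepcopy(base_params)
        p.mortality.life_table = make_flat_lifetable(0.5)
        p.mortality.validate()
        traj = simulate_patient(
            make_patient(ten_year_cvd_risk=0.4), ARM_USUAL, p, np.random.default_rng(4)
        )
        # the trajectory ends at death; nothing accrues beyond it
        assert traj.records[-1].state == "dead"
        assert len(traj.records) < 80

    def test_hf_cumulative_incidence_matches_annual_risk(self, base_params):
        """With only the HF hazard active (no death), one-year cumulative
        incidence over many replicates reproduces the annual risk 0.0358
        that the per-cycle probability was derived from."""
        from dataclasses import replace

        p = zero_hazard_params(base_params, qx=0.0)
        p.event_risks.hf_annual_risk = {b: 0.0358 for b in p.event_risks.hf_annual_risk}
        cfg = replace(p.simulation, max_horizon_years=1.0, n_patients=100_000)
        n = 100_000
        cohort = uniform_cohort(n)
        res = run_arm(cohort, ARM_USUAL, p, cfg)
        incidence = res.events_per_100k["hf"] / 100_000
        se = np.sqrt(0.0358 * (1 - 0.0358) / n)
        assert abs(incidence - 0.0358) < 3 * se


class TestRunArm:
    def test_empty_cohort_rejected(self, base_params):
        import pandas as pd

        with pytest.raises(ValueError):
            run_arm(pd.DataFrame(columns=uniform_cohort(1).columns), ARM_USUAL, base_params)

    def test_identical_seeds_identical_results(self, base_params):
        cohort = uniform_cohort(500, ten_year_cvd_risk=0.4)
        a = run_arm(cohort, ARM_REDUCTION, base_params)
        b = run_arm(cohort, ARM_REDUCTION, base_params)
        assert a.mean_cost == b.mean_cost
        assert a.mean_qaly == b.mean_qaly
        assert a.events_per_100k == b.events_per_100k

    def test_null_effect_equal_costs_gives_identical_arms(self, params):
        """With no BP difference and the reduction-specific costs removed,
        common random numbers make the two arms exactly equal."""
        params.treatment_effect.delta_sbp_mmhg = 0.0
        params.costs.safety_visit_cost = 0.0
        params.costs.reinstatement_visit_cost = 0.0
        params.costs.cost_per_drug_per_cycle = 0.0
        cohort = uniform_cohort(2000, ten_year_cvd_risk=0.4)
        usual = run_arm(cohort, ARM_USUAL, params)
        red = run_arm(cohort, ARM_REDUCTION, params)
        assert usual.mean_cost == pytest.approx(red.mean_cost, abs=1e-9)
        assert usual.mean_qaly == pytest.approx(red.mean_qaly, abs=1e-12)

    def test_se_scales_with_sqrt_n(self, base_params):
        cohort_small = uniform_cohort(1000, ten_year_cvd_risk=0.4)
        cohort_large = uniform_cohort(16000, ten_year_cvd_risk=0.4)
        small = run_arm(cohort_small, ARM_USUAL, base_params)
        large = run_arm(cohort_large, ARM_USUAL, base_params)
        assert small.se_qaly / large.se_qaly == pytest.approx(4.0, rel=0.25)

    def test_reduction_increases_hf_and_stroke_events(self, base_params):
        """RRs above 1 for HF and stroke/TIA mean more of those events under
        medication reduction, and the protective adverse-event RR means
        fewer drug-related events — the directional pattern reported for
        this model."""
        from dataclasses import replace

        cohort = uniform_cohort(20_000, ten_year_cvd_risk=0.4)
        cfg = replace(base_params.simulation, seed=77)
        usual = run_arm(cohort, ARM_USUAL, base_params, cfg)
        red = run_arm(cohort, ARM_REDUCTION, base_params, cfg)
        assert red.events_per_100k["hf"] > usual.events_per_100k["hf"]
        assert red.events_per_100k["stroke_tia"] > usual.events_per_100k["stroke_tia"]
        assert red.events_per_100k["serious_ae"] < usual.events_per_100k["serious_ae"]
        assert red.events_per_100k["minor_ae"] < usual.events_per_100k["minor_ae"]


def matrix_chain_expectation(params, patient_utility, qx, hf_cycle_prob, smr_hf,
                             recurring_cost, acute_hf, longterm_hf, n_cycles=80):
    """Independent oracle: exact expected discounted cost and QALYs of the
    three-state chain (event-free -> post-HF -> dead) evaluated by forward
    probability propagation, mirroring the engine's accounting conventions
    (event cycle: new-state utility + acute cost; long-term cost from the
    next cycle; death cycle: half the recurring accrual at the pre-death
    state)."""
    cl = 0.25
    rate = 0.035
    u_free = patient_utility
    u_hf = patient_utility * params.utilities.state_multipliers["hf"]
    p_death_free = 1 - (1 - qx) ** cl
    p_death_hf = 1 - (1 - qx) ** (smr_hf * cl)

    # engine's independent-cause multinomial combination from the free state
    p_none = (1 - p_death_free) * (1 - hf_cycle_prob)
    tot = p_death_free + hf_cycle_prob
    if tot > 0:
        q = 1 - p_none
        c_death = q * p_death_free / tot
        c_hf = q * hf_cycle_prob / tot
    else:
        c_death = c_hf = 0.0
    c_stay = 1 - c_death - c_hf

    pi_free, pi_hf = 1.0, 0.0
    e_qaly = e_cost = 0.0
    for k in range(n_cycles):
        df = (1 + rate) ** (-(k + 0.5) * cl)
        # from event-free
        q_free = (
            c_stay * u_free * cl
            + c_hf * u_hf * cl
            + c_death * 0.5 * u_free * cl
        )
        cost_free = (
            c_stay * recurring_cost
            + c_hf * (recurring_cost + acute_hf)
            + c_death * 0.5 * recurring_cost
        )
        # from post-HF (long-term cost applies: state at cycle start is HF)
        q_hf = (1 - p_death_hf) * u_hf * cl + p_death_hf * 0.5 * u_hf * cl
        cost_hf = (1 - p_death_hf) * (recurring_cost + longterm_hf) + p_death_hf * 0.5 * (
            recurring_cost + longterm_hf
        )
        e_qaly += df * (pi_free * q_free + pi_hf * q_hf)
        e_cost += df * (pi_free * cost_free + pi_hf * cost_hf)
        pi_free, pi_hf = pi_free * c_stay, pi_free * c_hf + pi_hf * (1 - p_death_hf)
    return e_cost, e_qaly


class TestCohortModelOracle:
    def test_microsim_matches_matrix_evaluation(self, base_params):
        """On a reduced fixed-hazard model (one patient type, flat
        mortality, HF as the only event) the microsimulation means converge
        to the exact state-transition expectation within 4 Monte-Carlo SEs."""
        qx, hf_annual = 0.06, 0.0358
        p = zero_hazard_params(base_params, qx=qx)
        p.event_risks.hf_annual_risk = {b: hf_annual for b in p.event_risks.hf_annual_risk}

        n = 20_000
        cohort = uniform_cohort(n)
        res = run_arm(cohort, ARM_USUAL, p)

        c = p.costs
        recurring = 0.8 * c.cost_per_consultation + 2 * c.cost_per_drug_per_cycle
        hf_cycle = 1 - (1 - hf_annual) ** 0.25
        e_cost, e_qaly = matrix_chain_expectation(
            p, 0.769, qx, hf_cycle, p.mortality.smr["hf"], recurring,
            c.acute_event_costs["hf"], c.longterm_event_costs_per_cycle["hf"],
        )
        assert abs(res.mean_qaly - e_qaly) < 4 * res.se_qaly
        assert abs(res.mean_cost - e_cost) < 4 * res.se_cost


class TestRunBaseCase:
    def test_paired_arms_and_classification(self, base_params):
        from dataclasses import replace

        cfg = replace(base_params.simulation, n_patients=3000, seed=123)
        usual, red, res = run_base_case(base_params, cfg)
        assert usual.n == red.n == 3000
        assert res.delta_cost == pytest.approx(usual.mean_cost - red.mean_cost)
        assert res.delta_qaly == pytest.approx(usual.mean_qaly - red.mean_qaly)
        assert res.label in {"tradeoff", "dominant", "dominated", "equivalent"}

    def test_qalys_bounded_by_discounted_lifeyears(self, base_params):
        from dataclasses import replace

        cfg = replace(base_params.simulation, n_patients=1000, seed=5)
        usual, red, _ = run_base_case(base_params, cfg)
        k = np.arange(80)
        annuity = (0.25 * 1.035 ** (-(k + 0.5) * 0.25)).sum()
        assert usual.mean_qaly < annuity
        assert red.mean_qaly < annuity
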