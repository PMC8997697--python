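import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from deprescribe import (
    PSAResult,
    Scenario,
    bisect_threshold,
    compute_ceac,
    compute_icer,
    run_psa,
    run_scenarios,
)
from tests.conftest import uniform_cohort


class TestComputeICER:
    def test_published_base_case_arithmetic(self):
        """Usual care (4745, 3.405) vs reduction (4560, 3.343): increments
        185 and 0.062, quotient ~2984 (the source rounds from unrounded
        simulation output to 2,975)."""
        res = compute_icer(4745.0, 3.405, 4560.0, 3.343)
        assert res.delta_cost == pytest.approx(185.0)
        assert res.delta_qaly == pytest.approx(0.062)
        assert res.icer == pytest.approx(185.0 / 0.062, rel=1e-12)
        assert res.icer == pytest.approx(2983.9, abs=0.1)
        assert res.label == "tradeoff"

    def test_equivalent(self):
        assert compute_icer(100.0, 2.0, 100.0, 2.0).label == "equivalent"

    def test_dominance(self):
        res = compute_icer(90.0, 2.1, 100.0, 2.0)
        assert res.label == "dominant"
        assert res.icer is None
        assert compute_icer(100.0, 2.0, 90.0, 2.1).label == "dominated"

    @settings(max_examples=50, derandomize=True)
    @given(
        ca=st.floats(0, 1e5), qa=st.floats(0, 20), cb=st.floats(0, 1e5), qb=st.floats(0, 20)
    )
    def test_antisymmetry(self, ca, qa, cb, qb):
        ab = compute_icer(ca, qa, cb, qb)
        ba = compute_icer(cb, qb, ca, qa)
        flip = {"dominant": "dominated", "dominated": "dominant",
                "tradeoff": "tradeoff", "equivalent": "equivalent"}
        assert ba.label == flip[ab.label]
        if ab.label == "tradeoff":
            assert abs(ba.icer) == pytest.approx(abs(ab.icer), rel=1e-12)


class TestCEAC:
    def test_single_pair_worked_example(self):
        psa = PSAResult(np.array([185.0]), np.array([0.062]), 1, 0)
        curve = compute_ceac(psa, [20_000.0])
        # NMB difference 20,000 x 0.062 - 185 = 1,055 > 0: usual care preferred
        assert curve.p_usual_care[0] == 1.0
        assert curve.p_reduction[0] == 0.0

    def test_wtp_zero_decided_by_cost_alone(self):
        psa = PSAResult(np.array([185.0, -50.0]), np.array([0.062, 0.01]), 2, 0)
        curve = compute_ceac(psa, [0.0])
        # usual care wins only where it is cheaper (delta cost < 0)
        assert curve.p_usual_care[0] == 0.5

    def test_symmetric_cloud_gives_half(self):
        d = np.array([100.0, -100.0, 40.0, -40.0])
        q = np.array([0.1, -0.1, 0.02, -0.02])
        curve = compute_ceac(PSAResult(d, q, 4, 0), np.linspace(0, 50_000, 11))
        assert np.allclose(curve.p_usual_care, 0.5)

    def test_ties_split_half(self):
        psa = PSAResult(np.array([200.0]), np.array([0.01]), 1, 0)
        curve = compute_ceac(psa, [20_000.0])  # NMB difference exactly 0
        assert curve.p_usual_care[0] == 0.5

    def test_monotone_and_sums_to_one(self):
        """When the QALY increment has constant sign across iterations the
        more-effective strategy's curve is non-decreasing in WTP, and the
        two curves always sum to 1."""
        rng = np.random.default_rng(8)
        dq = np.abs(rng.normal(0.05, 0.02, 400))  # usual care always more effective
        dc = rng.normal(150, 200, 400)
        curve = compute_ceac(PSAResult(dc, dq, 400, 0), np.linspace(0, 100_000, 51))
        assert (np.diff(curve.p_usual_care) >= -1e-12).all()
        assert np.allclose(curve.p_usual_care + curve.p_reduction, 1.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            compute_ceac(PSAResult(np.array([1.0]), np.array([0.1]), 1, 0), [])


class TestThresholdSearch:
    def test_linear_stub_closed_form(self):
        """ICER(x) = 10,000 x crosses WTP 20,000 at exactly x = 2."""
        res = bisect_threshold(lambda x: 10_000.0 * x, 20_000.0, (0.5, 5.0), icer_tol=1.0)
        assert res.threshold == pytest.approx(2.0, abs=1e-4)
        assert res.converged
        assert abs(res.icer_at_threshold - 20_000.0) <= 1.0

    def test_stable_to_bracket_refinement(self):
        f = lambda x: 10_000.0 * x
        first = bisect_threshold(f, 20_000.0, (0.5, 5.0), icer_tol=1.0)
        refined = bisect_threshold(
            f, 20_000.0, (first.threshold * 0.9, first.threshold * 1.1), icer_tol=1.0
        )
        assert refined.threshold == pytest.approx(first.threshold, abs=1e-3)

    def test_no_sign_change_is_diagnostic_failure(self):
        with pytest.raises(ValueError, match="no sign change"):
            bisect_threshold(lambda x: 10_000.0 * x, 20_000.0, (3.0, 5.0))

    def test_simulation_threshold_on_sae_risk(self, base_params):
        """Raising the baseline serious-adverse-event risk favours the
        reduction arm (its protective RR saves more events), pushing the
        usual-care ICER up through the willingness-to-pay."""
        from deprescribe import threshold_search

        cfg = replace(base_params.simulation, n_patients=4000, seed=31)
        cohort = uniform_cohort(4000, ten_year_cvd_risk=0.35)
        res = threshold_search(
            base_params, "event_risks.sae_annual_risk", 20_000.0, (0.0174, 0.9),
            cfg, cohort=cohort, icer_tol=500.0,
        )
        assert 0.0174 < res.threshold < 0.9
        assert res.converged
        assert abs(res.icer_at_threshold - 20_000.0) <= 500.0


class TestPSA:
    def test_fixed_distributions_fixed_cohort_identical_iterations(self, params):
        from deprescribe.parameters import PSADistributionSpec, get_by_path

        params.psa_specs = {
            path: PSADistributionSpec("fixed", {"value": float(get_by_path(params, path))})
            for path in params.psa_specs
        }
        cfg = replace(params.simulation, n_patients=300, seed=9)
        res = run_psa(params, cfg, n_iterations=4, fresh_cohort_per_iteration=False)
        assert np.ptp(res.delta_costs) == 0.0
        assert np.ptp(res.delta_qalys) == 0.0

    def test_reproducible_from_master_seed(self, base_params):
        cfg = replace(base_params.simulation, n_patients=200, seed=55)
        a = run_psa(base_params, cfg, n_iterations=5)
        b = run_psa(base_params, cfg, n_iterations=5)
        assert np.array_equal(a.delta_costs, b.delta_costs)
        assert np.array_equal(a.delta_qalys, b.delta_qalys)

    def test_pair_count_equals_iterations(self, base_params):
        cfg = replace(base_params.simulation, n_patients=100, seed=3)
        res = run_psa(base_params, cfg, n_iterations=7)
        assert res.n_iterations == 7
        assert len(res.delta_costs) == len(res.delta_qalys) == 7


class TestScenarios:
    def test_null_scenario_equalizes_qalys(self, params):
        params.costs.safety_visit_cost = 0.0
        params.costs.reinstatement_visit_cost = 0.0
        params.costs.cost_per_drug_per_cycle = 0.0
        cfg = replace(params.simulation, n_patients=1500, seed=2)
        sc = Scenario(
            "null",
            overrides={
                f"treatment_effect.{rr}": 1.0
                for rr in ("rr_chd", "rr_stroke_tia", "rr_hf", "rr_sae", "rr_minor")
            },
        )
        table = run_scenarios(params, [sc], cfg)
        assert table.loc[0, "delta_qaly"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc[0, "delta_cost"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc[0, "label"] == "equivalent"

    def test_shorter_effect_duration_shrinks_qaly_gap(self, base_params):
        cfg = replace(base_params.simulation, n_patients=20_000, seed=13)
        table = run_scenarios(
            base_params,
            [
                Scenario("lifetime"),
                Scenario("1y", overrides={"treatment_effect.effect_duration_years": 1.0}),
            ],
            cfg,
        )
        gap = dict(zip(table["scenario"], table["delta_qaly"].abs()))
        assert gap["1y"] < gap["lifetime"]

    def test_five_year_horizon_bounded_by_annuity(self, base_params):
        cfg = replace(base_params.simulation, n_patients=2000, seed=21)
        table = run_scenarios(
            base_params,
            [Scenario("5y", config_overrides={"max_horizon_years": 5.0})],
            cfg,
        )
        k = np.arange(20)
        bound = (0.25 * 1.035 ** (-(k + 0.5) * 0.25)).sum()
        assert table.loc[0, "qaly_usual_care"] <= bound
        assert table.loc[0, "qaly_reduction"] <= bound

    def test_unknown_override_path_rejected(self, base_params):
        from deprescribe.parameters import ParameterError

        cfg = replace(base_params.simulation, n_patients=100)
        with pytest.raises(ParameterError):
            run_scenarios(
                base_params, [Scenario("bad", overrides={"treatment_effect.nope": 1.0})], cfg
            )

    def test_subgroup_filters_shrink_cohort(self, base_params):
        cfg = replace(base_params.simulation, n_patients=2000, seed=6)
        table = run_scenarios(
            base_params,
            [Scenario("frail", cohort_filter="frail"), Scenario("fit", cohort_filter="fit")],
            cfg,
        )
        assert table["n"].sum() == 2000
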