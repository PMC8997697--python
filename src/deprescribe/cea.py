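"""Cost-effectiveness analytics.

Incremental analysis (ICER and dominance classification), probabilistic
sensitivity analysis (PSA) orchestration, cost-effectiveness acceptability
curves (CEAC), noise-controlled threshold searches, and the deterministic
scenario runner.

Sign convention throughout: increments are usual care minus medication
reduction, so a positive incremental cost and positive incremental QALYs
mean usual care is more expensive and more effective, and the ICER is the
extra cost per QALY gained by staying on full medication.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import risk_engine as re_
from .cohort import CohortSpec, generate_cohort
from .microsim import run_arm
from .parameters import (
    ModelParameters,
    ParameterError,
    SimulationConfig,
    draw_psa_parameters,
    set_by_path,
)

__all__ = [
    "CEAResult",
    "PSAResult",
    "CEACCurve",
    "ThresholdResult",
    "Scenario",
    "compute_icer",
    "run_psa",
    "compute_ceac",
    "bisect_threshold",
    "threshold_search",
    "run_scenarios",
    "standard_scenarios",
]


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of two strategies (A minus B)."""

    cost_a: float
    qaly_a: float
    cost_b: float
    qaly_b: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str  # dominant | dominated | tradeoff | equivalent (for strategy A)
    reference: str = "usual_care minus reduction"


def compute_icer(
    cost_a: float,
    qaly_a: float,
    cost_b: float,
    qaly_b: float,
    cost_tol: float = 1e-6,
    qaly_tol: float = 1e-9,
) -> CEAResult:
    """Classify strategy A against strategy B.

    ``equivalent`` when both increments are within tolerance of zero;
    ``dominant``/``dominated`` when A is (weakly) better/worse on both
    axes; otherwise a ``tradeoff`` with ICER = delta cost / delta QALYs.
    Degenerate cases are labelled, never raised.
    """
    dc = cost_a - cost_b
    dq = qaly_a - qaly_b
    if abs(dc) <= cost_tol and abs(dq) <= qaly_tol:
        return CEAResult(cost_a, qaly_a, cost_b, qaly_b, dc, dq, None, "equivalent")
    if dc <= cost_tol and dq >= -qaly_tol:
        return CEAResult(cost_a, qaly_a, cost_b, qaly_b, dc, dq, None, "dominant")
    if dc >= -cost_tol and dq <= qaly_tol:
        return CEAResult(cost_a, qaly_a, cost_b, qaly_b, dc, dq, None, "dominated")
    return CEAResult(cost_a, qaly_a, cost_b, qaly_b, dc, dq, dc / dq, "tradeoff")


@dataclass
class PSAResult:
    """Cloud of per-iteration incremental (cost, QALY) pairs,
    usual care minus reduction."""

    delta_costs: np.ndarray
    delta_qalys: np.ndarray
    n_iterations: int
    n_patients: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "delta_cost": self.delta_costs,
                "delta_qaly": self.delta_qalys,
            }
        )


def run_psa(
    params: ModelParameters,
    config: SimulationConfig | None = None,
    n_iterations: int = 1000,
    cohort_spec: CohortSpec | None = None,
    fresh_cohort_per_iteration: bool = True,
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Each iteration redraws every uncertain parameter from its PSA
    distribution, generates a fresh cohort (parameter and first-order
    uncertainty; set ``fresh_cohort_per_iteration=False`` to pin the
    cohort), runs both arms under common random numbers and records the
    incremental pair.  Fully reproducible from ``config.seed``.
    """
    if config is None:
        config = params.simulation
    if n_iterations < 1:
        raise ValueError("need at least one PSA iteration")
    if cohort_spec is None:
        cohort_spec = CohortSpec(
            maintain_reduction_prob=params.treatment_effect.maintain_reduction_prob
        )

    master = np.random.SeedSequence(config.seed)
    children = master.spawn(n_iterations + 1)
    fixed_cohort = None
    if not fresh_cohort_per_iteration:
        fixed_cohort = generate_cohort(
            cohort_spec, config.n_patients, np.random.default_rng(children[-1])
        )

    d_costs = np.empty(n_iterations)
    d_qalys = np.empty(n_iterations)
    for i in range(n_iterations):
        sub = children[i].spawn(2)
        drawn = draw_psa_parameters(params, np.random.default_rng(sub[0]))
        cohort = (
            generate_cohort(cohort_spec, config.n_patients, np.random.default_rng(sub[1]))
            if fresh_cohort_per_iteration
            else fixed_cohort
        )
        # the within-simulation stream is pinned across iterations (common
        # random numbers at the PSA level too): iteration-to-iteration
        # variation then reflects parameter and cohort uncertainty only
        usual = run_arm(cohort, re_.ARM_USUAL, drawn, config, keep_patient_level=False)
        red = run_arm(cohort, re_.ARM_REDUCTION, drawn, config, keep_patient_level=False)
        d_costs[i] = usual.mean_cost - red.mean_cost
        d_qalys[i] = usual.mean_qaly - red.mean_qaly
    return PSAResult(d_costs, d_qalys, n_iterations, config.n_patients)


@dataclass
class CEACCurve:
    """P(strategy maximizes net monetary benefit) over a WTP grid."""

    wtp: np.ndarray
    p_usual_care: np.ndarray
    p_reduction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp, "p_usual_care": self.p_usual_care, "p_reduction": self.p_reduction}
        )


def compute_ceac(psa: PSAResult, wtp_grid) -> CEACCurve:
    """At each willingness-to-pay λ, the fraction of PSA iterations in which
    usual care has the higher net monetary benefit (λ·ΔQ − ΔC > 0 with
    increments usual minus reduction); exact ties split 0.5/0.5."""
    wtp = np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ValueError("WTP grid must be non-empty")
    if psa.n_iterations == 0:
        raise ValueError("empty PSA result")
    nmb_diff = wtp[:, None] * psa.delta_qalys[None, :] - psa.delta_costs[None, :]
    p_usual = (nmb_diff > 0).mean(axis=1) + 0.5 * (nmb_diff == 0).mean(axis=1)
    return CEACCurve(wtp=wtp, p_usual_care=p_usual, p_reduction=1.0 - p_usual)


@dataclass(frozen=True)
class ThresholdResult:
    parameter_path: str
    bracket: tuple[float, float]
    threshold: float
    icer_at_threshold: float
    wtp: float
    converged: bool
    iterations: int


def bisect_threshold(
    icer_fn,
    wtp: float,
    bracket: tuple[float, float],
    icer_tol: float = 250.0,
    xtol: float = 1e-6,
    max_iter: int = 100,
    parameter_path: str = "<callable>",
) -> ThresholdResult:
    """Bisection for the parameter value at which ``icer_fn`` crosses the
    willingness-to-pay.  ``icer_fn`` must be deterministic (fixed-seed
    simulations or a closed form); the bracket must produce a sign change
    of ICER − WTP, which is checked up front."""
    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo = icer_fn(lo) - wtp
    f_hi = icer_fn(hi) - wtp
    if f_lo == 0.0:
        return ThresholdResult(parameter_path, (lo, hi), lo, wtp, wtp, True, 0)
    if f_hi == 0.0:
        return ThresholdResult(parameter_path, (lo, hi), hi, wtp, wtp, True, 0)
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"no sign change of ICER - WTP over bracket [{lo}, {hi}]: "
            f"f(lo)={f_lo:.1f}, f(hi)={f_hi:.1f}"
        )
    mid = 0.5 * (lo + hi)
    f_mid = icer_fn(mid) - wtp
    for it in range(1, max_iter + 1):
        if abs(f_mid) <= icer_tol or (hi - lo) <= xtol * max(1.0, abs(mid)):
            return ThresholdResult(
                parameter_path, tuple(bracket), mid, f_mid + wtp, wtp,
                abs(f_mid) <= icer_tol, it,
            )
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
        mid = 0.5 * (lo + hi)
        f_mid = icer_fn(mid) - wtp
    return ThresholdResult(
        parameter_path, tuple(bracket), mid, f_mid + wtp, wtp, abs(f_mid) <= icer_tol, max_iter
    )


def threshold_search(
    params: ModelParameters,
    parameter_path: str,
    wtp: float,
    bracket: tuple[float, float],
    config: SimulationConfig | None = None,
    cohort: pd.DataFrame | None = None,
    icer_tol: float = 250.0,
) -> ThresholdResult:
    """Find the value of one model parameter at which the usual-care ICER
    equals the willingness-to-pay.

    Runs on a single fixed cohort with common random numbers so the ICER is
    a deterministic function of the searched parameter and bisection can
    converge despite Monte-Carlo noise.
    """
    if config is None:
        config = params.simulation
    if cohort is None:
        spec = CohortSpec(maintain_reduction_prob=params.treatment_effect.maintain_reduction_prob)
        cohort = generate_cohort(spec, config.n_patients, np.random.default_rng(config.seed))

    def increments(x: float) -> tuple[float, float]:
        trial = params.copy()
        set_by_path(trial, parameter_path, float(x))
        trial.validate()
        usual = run_arm(cohort, re_.ARM_USUAL, trial, config, keep_patient_level=False)
        red = run_arm(cohort, re_.ARM_REDUCTION, trial, config, keep_patient_level=False)
        return usual.mean_cost - red.mean_cost, usual.mean_qaly - red.mean_qaly

    # Bisection runs on the net-monetary-benefit difference
    # g(x) = WTP * dQ(x) - dC(x), whose root is exactly the point where the
    # usual-care ICER equals the WTP; unlike the raw ICER, g has no pole
    # where dQ changes sign, so the sign-change check is robust.
    def g(x: float) -> tuple[float, float, float]:
        dc, dq = increments(x)
        return wtp * dq - dc, dc, dq

    lo, hi = float(bracket[0]), float(bracket[1])
    g_lo, _, _ = g(lo)
    g_hi, _, _ = g(hi)
    if np.sign(g_lo) == np.sign(g_hi) and g_lo != 0.0 and g_hi != 0.0:
        raise ValueError(
            f"no sign change of the net-benefit difference over bracket [{lo}, {hi}]: "
            f"g(lo)={g_lo:.2f}, g(hi)={g_hi:.2f}"
        )
    mid = 0.5 * (lo + hi)
    it = 0
    for it in range(1, 61):
        g_mid, dc, dq = g(mid)
        if g_mid == 0.0 or (hi - lo) <= 1e-6 * max(1.0, abs(mid)):
            break
        if np.sign(g_mid) == np.sign(g_lo):
            lo, g_lo = mid, g_mid
        else:
            hi = mid
        mid = 0.5 * (lo + hi)
    g_mid, dc, dq = g(mid)
    icer_at = dc / dq if dq != 0.0 else float("inf")
    return ThresholdResult(
        parameter_path, tuple(bracket), mid, icer_at, wtp,
        abs(icer_at - wtp) <= icer_tol, it,
    )


# ---------------------------------------------------------------------------
# Deterministic sensitivity / scenario runner
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """One deterministic sensitivity run.

    ``overrides`` maps dotted parameter paths to replacement values;
    ``config_overrides`` replaces SimulationConfig fields (e.g. a 5-year
    horizon); ``cohort_filter`` restricts the shared cohort to a subgroup
    (``frail``/``fit`` or ``cvd0``/``cvd1``/``cvd2``); ``risk_multiplier``
    scales every patient's 10-year CVD risk (0.5 = halved risk).
    """

    name: str
    overrides: dict[str, object] = field(default_factory=dict)
    config_overrides: dict[str, object] = field(default_factory=dict)
    cohort_filter: str | None = None
    risk_multiplier: float = 1.0


_FILTERS = {
    "frail": lambda df: df["frailty"] == "frail",
    "fit": lambda df: df["frailty"] == "fit",
    "cvd0": lambda df: df["n_prior_cvd"] == 0,
    "cvd1": lambda df: df["n_prior_cvd"] == 1,
    "cvd2": lambda df: df["n_prior_cvd"] == 2,
}


def run_scenarios(
    params: ModelParameters,
    scenario_specs: list[Scenario],
    config: SimulationConfig | None = None,
    cohort: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evaluate each scenario on a shared cohort and seed; one row per
    scenario with per-arm cost/QALYs, increments, ICER and label."""
    if config is None:
        config = params.simulation
    if cohort is None:
        spec = CohortSpec(maintain_reduction_prob=params.treatment_effect.maintain_reduction_prob)
        cohort = generate_cohort(spec, config.n_patients, np.random.default_rng(config.seed))

    rows = []
    for sc in scenario_specs:
        trial = params.copy()
        for path, value in sc.overrides.items():
            set_by_path(trial, path, value)
        trial.validate()
        cfg = replace(config, **sc.config_overrides) if sc.config_overrides else config
        sub = cohort
        if sc.cohort_filter is not None:
            if sc.cohort_filter not in _FILTERS:
                raise ParameterError(sc.cohort_filter, "unknown cohort filter")
            sub = cohort[_FILTERS[sc.cohort_filter](cohort)].reset_index(drop=True)
        if sc.risk_multiplier != 1.0:
            sub = sub.copy()
            sub["ten_year_cvd_risk"] = np.clip(
                sub["ten_year_cvd_risk"] * sc.risk_multiplier, 0.0, 1.0
            )
        usual = run_arm(sub, re_.ARM_USUAL, trial, cfg, keep_patient_level=False)
        red = run_arm(sub, re_.ARM_REDUCTION, trial, cfg, keep_patient_level=False)
        res = compute_icer(usual.mean_cost, usual.mean_qaly, red.mean_cost, red.mean_qaly)
        rows.append(
            {
                "scenario": sc.name,
                "n": len(sub),
                "cost_usual_care": res.cost_a,
                "qaly_usual_care": res.qaly_a,
                "cost_reduction": res.cost_b,
                "qaly_reduction": res.qaly_b,
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_qaly,
                "icer": res.icer,
                "label": res.label,
            }
        )
    return pd.DataFrame(rows)


def standard_scenarios(params: ModelParameters) -> list[Scenario]:
    """The deterministic sensitivity set: RR confidence-interval bounds,
    no-effect RRs, halved CVD risk, the lower-CI BP difference, shortened
    effect durations, a 5-year horizon, and frailty / comorbidity
    subgroups."""
    ci = params.ci
    out = [Scenario("base_case")]
    for which, idx in (("lower", 0), ("upper", 1)):
        out.append(
            Scenario(
                f"rr_cvd_{which}_ci",
                overrides={
                    f"treatment_effect.{rr}": ci[f"treatment_effect.{rr}"][idx]
                    for rr in ("rr_chd", "rr_stroke_tia", "rr_hf")
                },
            )
        )
        out.append(
            Scenario(
                f"rr_ae_{which}_ci",
                overrides={
                    f"treatment_effect.{rr}": ci[f"treatment_effect.{rr}"][idx]
                    for rr in ("rr_sae", "rr_minor")
                },
            )
        )
    out.append(
        Scenario(
            "rr_all_one",
            overrides={
                f"treatment_effect.{rr}": 1.0
                for rr in ("rr_chd", "rr_stroke_tia", "rr_hf", "rr_sae", "rr_minor")
            },
        )
    )
    out.append(Scenario("halved_cvd_risk", risk_multiplier=0.5))
    out.append(Scenario("delta_sbp_lower_ci", overrides={"treatment_effect.delta_sbp_mmhg": 1.0}))
    for years in (1, 2, 5, 10):
        out.append(
            Scenario(
                f"effect_duration_{years}y",
                overrides={"treatment_effect.effect_duration_years": float(years)},
            )
        )
    out.append(Scenario("horizon_5y", config_overrides={"max_horizon_years": 5.0}))
    for flt in ("fit", "frail", "cvd0", "cvd1", "cvd2"):
        out.append(Scenario(f"subgroup_{flt}", cohort_filter=flt))
    return out
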