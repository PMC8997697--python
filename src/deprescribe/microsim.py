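"""Discrete-time patient-level simulation engine.

Each patient walks through 3-month cycles to death or the model horizon
(base 20 years).  Within a cycle the competing causes — background death,
CHD event, cerebrovascular event, heart failure, serious drug-related
adverse event, minor adverse event — are combined into a single multinomial
draw via the independent-cause product construction: P(no event) is the
product of the per-cause survival probabilities and each cause receives a
share of the event mass proportional to its marginal probability.  The
first serious event moves the patient permanently to a post-event state
with SMR-adjusted mortality; afterwards only death and minor adverse events
remain possible (no recurrent or subsequent serious events are modelled).

Events sit at cycle midpoints: the new state's utility multiplier and the
acute event cost apply in the event cycle, long-term post-event costs start
the following cycle, and the cycle in which a patient dies accrues half of
its recurring utility and cost.

The engine is vectorized across patients; both treatment arms can be run on
the same cohort with identical random streams (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import econ, risk_engine as re_
from .cohort import PatientProfile
from .parameters import ModelParameters, SimulationConfig

__all__ = [
    "CycleRecord",
    "Trajectory",
    "ArmResult",
    "simulate_patient",
    "run_arm",
    "run_base_case",
    "EVENT_CATEGORIES",
]

EVENT_CATEGORIES = ("hf", "chd", "stroke_tia", "serious_ae", "minor_ae")

# cause indices inside the per-cycle multinomial
_C_DEATH, _C_CHD, _C_CER, _C_HF, _C_SAE, _C_MINOR, _C_NONE = range(7)

_EVENT_STATE = {
    "mi": re_.STATE_MI,
    "acs": re_.STATE_ACS,
    "angina": re_.STATE_ANGINA,
    "stroke": re_.STATE_STROKE,
    "tia": re_.STATE_TIA,
    "hf": re_.STATE_HF,
    "serious_fall": re_.STATE_FALL,
    "aki": re_.STATE_AKI,
}
_STATE_EVENT = {v: k for k, v in _EVENT_STATE.items()}


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    state: str
    event: str | None
    cost: float
    qaly: float
    cost_discounted: float
    qaly_discounted: float


@dataclass
class Trajectory:
    """Per-patient event history with per-cycle economics."""

    records: list[CycleRecord] = field(default_factory=list)

    @property
    def total_cost_discounted(self) -> float:
        return sum(r.cost_discounted for r in self.records)

    @property
    def total_qaly_discounted(self) -> float:
        return sum(r.qaly_discounted for r in self.records)

    @property
    def final_state(self) -> str:
        return self.records[-1].state if self.records else "event-free"


@dataclass
class ArmResult:
    """Aggregated outcomes of one strategy arm."""

    arm: str
    n: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    events_per_100k: dict[str, float]
    run_key: tuple = ()
    patient_costs: np.ndarray | None = None
    patient_qalys: np.ndarray | None = None


def _state_vectors(params: ModelParameters):
    """Per-state lookup arrays indexed by integer state code."""
    smr = np.ones(10)
    mult = np.ones(10)
    longterm = np.zeros(10)
    for code, key in re_.SMR_KEYS.items():
        smr[code] = params.mortality.smr[key]
        longterm[code] = params.costs.longterm_event_costs_per_cycle.get(key, 0.0)
    for code, key in (
        (re_.STATE_MI, "mi"),
        (re_.STATE_ACS, "acs"),
        (re_.STATE_ANGINA, "angina"),
        (re_.STATE_STROKE, "stroke"),
        (re_.STATE_HF, "hf"),
        (re_.STATE_FALL, "serious_fall"),
    ):
        mult[code] = params.utilities.state_multipliers[key]
    mult[re_.STATE_DEAD] = 0.0
    return smr, mult, longterm


def _fraction_tables(params: ModelParameters):
    """Event-composition fractions as [sex(F=0,M=1), band(<85=0,85+=1)] arrays."""
    er = params.event_risks
    bands = ("75-84", "85+")
    p_mi = np.empty((2, 2))
    p_acs = np.empty((2, 2))
    p_stroke = np.empty((2, 2))
    for si, sex in enumerate(("F", "M")):
        for bi, band in enumerate(bands):
            p_mi[si, bi], p_acs[si, bi], _ = er.chd_type_fractions[sex][band]
            p_stroke[si, bi] = er.cerebro_type_fractions[sex][band][0]
    return p_mi, p_acs, p_stroke


def _simulate(
    cohort: pd.DataFrame,
    arm: str,
    params: ModelParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
    trace: bool = False,
):
    """Vectorized walk of the whole cohort through all cycles.

    Returns per-patient discounted costs/QALYs, event totals by category,
    and (with ``trace``) per-cycle records for each patient.
    """
    n = len(cohort)
    cl = config.cycle_length_years
    n_cycles = config.n_cycles
    er = params.event_risks
    reduction = arm == re_.ARM_REDUCTION

    age = cohort["age"].to_numpy(float).copy()
    male = (cohort["sex"] == "M").to_numpy()
    prior = cohort["n_prior_cvd"].to_numpy(int) > 0
    risk10 = cohort["ten_year_cvd_risk"].to_numpy(float)
    u0 = cohort["baseline_utility"].to_numpy(float)
    ndrugs = cohort["n_drugs"].to_numpy(int)

    # maintained-reduction flags: always consume one draw block so the two
    # arms' random streams stay aligned under common random numbers
    maint_draw = rng.random(n) < params.treatment_effect.maintain_reduction_prob
    if "maintained_reduction" in cohort.columns:
        vals = cohort["maintained_reduction"].to_numpy()
        missing = pd.isna(vals)
        filled = np.where(missing, False, vals)
        maintained = np.where(missing, maint_draw, filled.astype(bool))
    else:
        maintained = maint_draw

    smr_by_state, mult_by_state, longterm_by_state = _state_vectors(params)
    p_mi_tab, p_acs_tab, p_stroke_tab = _fraction_tables(params)
    hf_annual = np.array([er.hf_annual_risk[b] for b in ("80-84", "85-89", "90+")])
    dec = params.utilities.decrements_annual
    minor_decs = np.array([dec[k] for k in
                           ("hypotension", "syncope", "bradycardia", "electrolyte",
                            "nonserious_fall")])
    acute = params.costs.acute_event_costs
    acute_by_state = np.zeros(10)
    for code, key in _STATE_EVENT.items():
        acute_by_state[code] = acute.get(key, 0.0)
    acute_minor = acute.get("minor_ae", 0.0)
    c = params.costs
    w_chd, w_cer = er.chd_cerebro_split
    dfs = econ.discount_factors(config, n_cycles)

    state = np.zeros(n, dtype=int)
    cost_disc = np.zeros(n)
    qaly_disc = np.zeros(n)
    cost_undisc = np.zeros(n)
    qaly_undisc = np.zeros(n)
    event_totals = dict.fromkeys(EVENT_CATEGORIES, 0)

    if trace:
        tr_state = np.full((n_cycles, n), re_.STATE_DEAD, dtype=int)
        tr_event = np.full((n_cycles, n), -1, dtype=int)  # -1 none, codes as _EVENT_STATE, 100 minor, 99 death
        tr_cost = np.zeros((n_cycles, n))
        tr_qaly = np.zeros((n_cycles, n))
        tr_alive = np.zeros((n_cycles, n), dtype=bool)

    for k in range(n_cycles):
        # fixed-shape draws every cycle keep arm streams synchronized
        u_cause = rng.random(n)
        u_sub = rng.random(n)
        u_minor = rng.random(n)

        alive = state != re_.STATE_DEAD
        if not alive.any():
            continue

        elapsed = k * cl
        rr = re_.effective_rrs(params, arm, elapsed)

        iage = np.floor(age).astype(int)
        qx = params.mortality.annual_qx(iage, male)
        p_death = 1.0 - (1.0 - qx) ** (smr_by_state[state] * cl)

        free = state == re_.STATE_FREE
        mult_prior = np.where(prior, er.prior_cvd_multiplier, 1.0)
        p_cvd_base = 1.0 - (1.0 - risk10) ** (mult_prior * cl / 10.0)
        p_chd = np.clip(w_chd * p_cvd_base * rr["chd"], 0.0, 1.0) * free
        p_cer = np.clip(w_cer * p_cvd_base * rr["stroke_tia"], 0.0, 1.0) * free
        band3 = re_.hf_band_index(np.maximum(age, 80.0))
        p_hf = np.clip((1.0 - (1.0 - hf_annual[band3]) ** cl) * rr["hf"], 0.0, 1.0) * free
        p_sae = min(1.0, (1.0 - (1.0 - er.sae_annual_risk) ** cl) * rr["sae"]) * free
        p_minor = np.full(
            n, min(1.0, (1.0 - (1.0 - er.minor_ae_annual_risk) ** cl) * rr["minor"])
        )

        probs = np.stack([p_death, p_chd, p_cer, p_hf, p_sae, p_minor])
        p_none = np.prod(1.0 - probs, axis=0)
        tot = probs.sum(axis=0)
        scale = np.where(tot > 0.0, (1.0 - p_none) / np.where(tot > 0.0, tot, 1.0), 0.0)
        cum = np.cumsum(probs * scale, axis=0)
        cause = (u_cause[None, :] >= cum).sum(axis=0)
        cause = np.where(alive, cause, _C_NONE)

        # subtype classification
        si = male.astype(int)
        bi = (age >= 85.0).astype(int)
        p_mi = p_mi_tab[si, bi]
        p_acs = p_acs_tab[si, bi]
        p_stroke = p_stroke_tab[si, bi]

        new_state = state.copy()
        died = cause == _C_DEATH
        new_state[died] = re_.STATE_DEAD

        is_chd = cause == _C_CHD
        mi_sel = is_chd & (u_sub < p_mi)
        acs_sel = is_chd & ~mi_sel & (u_sub < p_mi + p_acs)
        ang_sel = is_chd & ~mi_sel & ~acs_sel
        new_state[mi_sel] = re_.STATE_MI
        new_state[acs_sel] = re_.STATE_ACS
        new_state[ang_sel] = re_.STATE_ANGINA

        is_cer = cause == _C_CER
        stroke_sel = is_cer & (u_sub < p_stroke)
        tia_sel = is_cer & ~stroke_sel
        new_state[stroke_sel] = re_.STATE_STROKE
        new_state[tia_sel] = re_.STATE_TIA

        hf_sel = cause == _C_HF
        new_state[hf_sel] = re_.STATE_HF

        sae_sel = cause == _C_SAE
        fall_sel = sae_sel & (u_sub < er.fall_aki_split[0])
        aki_sel = sae_sel & ~fall_sel
        new_state[fall_sel] = re_.STATE_FALL
        new_state[aki_sel] = re_.STATE_AKI

        minor_sel = (cause == _C_MINOR) & alive
        minor_idx = np.minimum((u_minor * len(minor_decs)).astype(int), len(minor_decs) - 1)

        event_totals["hf"] += int(hf_sel.sum())
        event_totals["chd"] += int(is_chd.sum())
        event_totals["stroke_tia"] += int(is_cer.sum())
        event_totals["serious_ae"] += int(sae_sel.sum())
        event_totals["minor_ae"] += int(minor_sel.sum())

        # --- utility: the new state applies in the event cycle; patients
        # dying this cycle accrue half a cycle at their pre-death state -----
        state_u = np.where(died, state, new_state)
        u_cycle = u0 * mult_by_state[state_u]
        if reduction and params.treatment_effect.reduction_utility_gain_annual:
            u_cycle = u_cycle + params.treatment_effect.reduction_utility_gain_annual
        u_cycle = np.where(state_u == re_.STATE_AKI, u_cycle - dec["aki"], u_cycle)
        u_cycle = np.where(tia_sel, u_cycle - dec["tia"] / 12.0 / cl, u_cycle)
        u_cycle = np.where(minor_sel, u_cycle - minor_decs[minor_idx] / 12.0 / cl, u_cycle)
        u_cycle = np.clip(u_cycle, 0.0, None)

        frac = np.where(died, 0.5, 1.0) * alive
        qaly_k = u_cycle * cl * frac

        # --- costs: long-term care keyed to the state at cycle start -------
        if reduction:
            if k == 0:
                drugs_k = ndrugs - 1
            else:
                drugs_k = np.where(maintained, ndrugs - 1, ndrugs)
        else:
            drugs_k = ndrugs
        recurring = (
            c.consultations_per_cycle * c.cost_per_consultation
            + drugs_k * c.cost_per_drug_per_cycle
            + longterm_by_state[state]
        )
        oneoff = np.zeros(n)
        if reduction and k == 0:
            oneoff += c.safety_visit_cost
        if reduction and k == 1:
            oneoff += np.where(maintained, 0.0, c.reinstatement_visit_cost)
        acute_k = np.zeros(n)
        serious_event = is_chd | is_cer | hf_sel | sae_sel
        acute_k[serious_event] = acute_by_state[new_state[serious_event]]
        acute_k[minor_sel] += acute_minor
        cost_k = recurring * frac + (oneoff + acute_k) * alive

        cost_disc += cost_k * dfs[k]
        qaly_disc += qaly_k * dfs[k]
        cost_undisc += cost_k
        qaly_undisc += qaly_k

        if trace:
            tr_alive[k] = alive
            tr_state[k] = new_state
            ev = np.full(n, -1, dtype=int)
            ev[died & alive] = 99
            ev[minor_sel] = 100
            for sel in (mi_sel, acs_sel, ang_sel, stroke_sel, tia_sel, hf_sel, fall_sel, aki_sel):
                ev[sel] = new_state[sel]
            tr_event[k] = ev
            tr_cost[k] = cost_k
            tr_qaly[k] = qaly_k

        state = new_state
        age = age + cl

    out = {
        "cost_disc": cost_disc,
        "qaly_disc": qaly_disc,
        "cost_undisc": cost_undisc,
        "qaly_undisc": qaly_undisc,
        "event_totals": event_totals,
        "dfs": dfs,
    }
    if trace:
        out["trace"] = (tr_alive, tr_state, tr_event, tr_cost, tr_qaly)
    return out


def _profile_frame(patient: PatientProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [patient.age],
            "sex": [patient.sex],
            "n_prior_cvd": [patient.n_prior_cvd],
            "ten_year_cvd_risk": [patient.ten_year_cvd_risk],
            "baseline_utility": [patient.baseline_utility],
            "frailty": [patient.frailty],
            "n_drugs": [patient.n_drugs],
            "maintained_reduction": [patient.maintained_reduction],
        }
    )


def simulate_patient(
    patient: PatientProfile,
    arm: str,
    params: ModelParameters,
    rng: np.random.Generator,
) -> Trajectory:
    """Walk a single patient through the model, returning their trajectory."""
    patient.validate()
    config = params.simulation
    res = _simulate(_profile_frame(patient), arm, params, config, rng, trace=True)
    tr_alive, tr_state, tr_event, tr_cost, tr_qaly = res["trace"]
    dfs = res["dfs"]
    records = []
    for k in range(config.n_cycles):
        if not tr_alive[k, 0]:
            break
        evcode = int(tr_event[k, 0])
        if evcode == -1:
            event = None
        elif evcode == 99:
            event = "death"
        elif evcode == 100:
            event = "minor_ae"
        else:
            event = _STATE_EVENT[evcode]
        records.append(
            CycleRecord(
                cycle=k,
                state=re_.STATE_NAMES[int(tr_state[k, 0])],
                event=event,
                cost=float(tr_cost[k, 0]),
                qaly=float(tr_qaly[k, 0]),
                cost_discounted=float(tr_cost[k, 0] * dfs[k]),
                qaly_discounted=float(tr_qaly[k, 0] * dfs[k]),
            )
        )
        if tr_state[k, 0] == re_.STATE_DEAD:
            break
    return Trajectory(records=records)


def _cohort_key(cohort: pd.DataFrame, config: SimulationConfig) -> tuple:
    return (len(cohort), config.seed, round(float(cohort["age"].sum()), 6))


def run_arm(
    cohort: pd.DataFrame,
    arm: str,
    params: ModelParameters,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    keep_patient_level: bool = True,
) -> ArmResult:
    """Simulate one strategy arm over a cohort and aggregate.

    With ``common_random_numbers`` on (default) each arm call builds its own
    generator from ``config.seed``, so both arms see identical random
    streams; otherwise the arm name perturbs the seed.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    if config is None:
        config = params.simulation
    if rng is None:
        if config.common_random_numbers:
            rng = np.random.default_rng(config.seed)
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 1 if arm == re_.ARM_REDUCTION else 0])
            )
    res = _simulate(cohort, arm, params, config, rng)
    n = len(cohort)
    costs, qalys = res["cost_disc"], res["qaly_disc"]
    per100k = {k: v / n * 100_000.0 for k, v in res["event_totals"].items()}
    return ArmResult(
        arm=arm,
        n=n,
        mean_cost=float(costs.mean()),
        mean_qaly=float(qalys.mean()),
        se_cost=float(costs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qalys.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        events_per_100k=per100k,
        run_key=_cohort_key(cohort, config),
        patient_costs=costs if keep_patient_level else None,
        patient_qalys=qalys if keep_patient_level else None,
    )


def run_base_case(
    params: ModelParameters,
    config: SimulationConfig | None = None,
    cohort: pd.DataFrame | None = None,
):
    """Run both strategy arms on one cohort (common random numbers) and
    return (usual-care ArmResult, reduction ArmResult, CEAResult)."""
    from .cea import compute_icer  # deferred: cea builds on this module
    from .cohort import CohortSpec, generate_cohort

    if config is None:
        config = params.simulation
    if cohort is None:
        spec = CohortSpec(maintain_reduction_prob=params.treatment_effect.maintain_reduction_prob)
        cohort = generate_cohort(spec, config.n_patients, np.random.default_rng(config.seed))
    usual = run_arm(cohort, re_.ARM_USUAL, params, config)
    reduction = run_arm(cohort, re_.ARM_REDUCTION, params, config)
    cea = compute_icer(usual.mean_cost, usual.mean_qaly, reduction.mean_cost, reduction.mean_qaly)
    return usual, reduction, cea
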