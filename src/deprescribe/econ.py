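"""Utility and cost accrual, discounting, half-cycle correction.

QALYs accrue as (utility index x cycle length); costs as the sum of routine
primary-care contact and prescription costs, one-off visit costs, acute
event costs in the event cycle and long-term post-event costs per cycle.
Future costs and outcomes are discounted at an annual rate (base 3.5%).
The half-cycle correction is implemented as midpoint discounting: the
cycle-k accrual is valued at time (k + 1/2) x cycle length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import PatientProfile
from .parameters import ModelParameters, SimulationConfig
from . import risk_engine as re_

__all__ = [
    "EconAccrual",
    "cycle_utility",
    "cycle_cost",
    "discount_factor",
    "discount_factors",
    "accrue",
    "drugs_on_regimen",
]

# state code -> utility-multiplier / cost-table key (states with no
# multiplier, e.g. post-TIA and post-AKI, keep the baseline score and are
# handled through decrements instead)
_MULT_KEYS = {
    re_.STATE_MI: "mi",
    re_.STATE_ACS: "acs",
    re_.STATE_ANGINA: "angina",
    re_.STATE_STROKE: "stroke",
    re_.STATE_HF: "hf",
    re_.STATE_FALL: "serious_fall",
}

_EVENT_KEYS = {
    re_.STATE_MI: "mi",
    re_.STATE_ACS: "acs",
    re_.STATE_ANGINA: "angina",
    re_.STATE_STROKE: "stroke",
    re_.STATE_TIA: "tia",
    re_.STATE_HF: "hf",
    re_.STATE_FALL: "serious_fall",
    re_.STATE_AKI: "aki",
}


@dataclass(frozen=True)
class EconAccrual:
    """One cycle's economics: raw and discounted cost and QALY increments."""

    utility: float
    cost: float
    discount: float
    qaly: float
    qaly_discounted: float
    cost_discounted: float


def cycle_utility(
    state: int,
    patient: PatientProfile,
    transient_events: list[str],
    params: ModelParameters,
) -> float:
    """Utility score in force for one cycle.

    Baseline utility times the post-event state multiplier; post-AKI
    subtracts an absolute decrement (annual value applied every cycle for
    life); transient one-month disutilities (TIA, minor adverse events
    occurring this cycle) subtract decrement/12 of a QALY, expressed here as
    a within-cycle average utility reduction decrement/12/cycle_length.
    Floored at zero.
    """
    u = patient.baseline_utility
    if state in _MULT_KEYS:
        u *= params.utilities.state_multipliers[_MULT_KEYS[state]]
    dec = params.utilities.decrements_annual
    if state == re_.STATE_AKI:
        u -= dec["aki"]
    cl = params.simulation.cycle_length_years
    for ev in transient_events:
        u -= dec[ev] * (1.0 / 12.0) / cl
    return max(0.0, u)


def drugs_on_regimen(patient: PatientProfile, arm: str, cycle: int) -> int:
    """Antihypertensive count being dispensed in a given cycle.

    Reduction-arm patients drop one drug at entry; those who do not maintain
    the reduction revert to their full regimen after the first cycle (the
    reinstatement visit is costed separately in :func:`cycle_cost`).
    """
    if arm != re_.ARM_REDUCTION:
        return patient.n_drugs
    if cycle == 0 or patient.maintained_reduction:
        return patient.n_drugs - 1
    return patient.n_drugs


def cycle_cost(
    state: int,
    patient: PatientProfile,
    arm: str,
    cycle: int,
    events: list[str],
    params: ModelParameters,
) -> float:
    """Cost (GBP) accrued in one cycle.

    ``state`` is the health state at cycle start (long-term post-event care
    costs begin the cycle after the event; the event cycle instead carries
    the acute cost of each event in ``events``).  Routine costs are primary
    care consultations (0.8 per 3-month cycle by default) and prescriptions;
    the reduction arm adds a one-off safety visit in cycle 0 and, for
    patients not maintaining the reduction, a reinstatement visit in cycle 1.
    """
    c = params.costs
    total = c.consultations_per_cycle * c.cost_per_consultation
    total += drugs_on_regimen(patient, arm, cycle) * c.cost_per_drug_per_cycle
    if state in _EVENT_KEYS:
        total += c.longterm_event_costs_per_cycle.get(_EVENT_KEYS[state], 0.0)
    if arm == re_.ARM_REDUCTION:
        if cycle == 0:
            total += c.safety_visit_cost
        if cycle == 1 and not patient.maintained_reduction:
            total += c.reinstatement_visit_cost
    for ev in events:
        total += c.acute_event_costs.get(ev, 0.0)
    return total


def discount_factor(time_years: float, rate: float):
    """Present-value factor (1 + rate)^(-t)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-np.asarray(time_years, dtype=float)) if np.ndim(
        time_years
    ) else (1.0 + rate) ** (-time_years)


def discount_factors(config: SimulationConfig, n_cycles: int | None = None) -> np.ndarray:
    """Per-cycle discount factors; cycle midpoints when the half-cycle
    correction is on, cycle starts when off."""
    if n_cycles is None:
        n_cycles = config.n_cycles
    k = np.arange(n_cycles, dtype=float)
    t = (k + 0.5) * config.cycle_length_years if config.half_cycle_correction else (
        k * config.cycle_length_years
    )
    return (1.0 + config.discount_rate_annual) ** (-t)


def accrue(
    cycle: int,
    utility: float,
    cost: float,
    config: SimulationConfig,
    fraction: float = 1.0,
) -> EconAccrual:
    """Economics for one trajectory cycle.

    ``fraction`` scales the accrual for partial cycles (0.5 in the cycle a
    patient dies, since events sit at cycle midpoints).  QALY increment is
    utility x cycle length x fraction; discounting is evaluated at the cycle
    midpoint when the half-cycle correction is on, at cycle start otherwise.
    """
    cl = config.cycle_length_years
    t = (cycle + 0.5) * cl if config.half_cycle_correction else cycle * cl
    df = float(discount_factor(t, config.discount_rate_annual))
    qaly = utility * cl * fraction
    cost_f = cost * fraction
    return EconAccrual(
        utility=utility,
        cost=cost_f,
        discount=df,
        qaly=qaly,
        qaly_discounted=qaly * df,
        cost_discounted=cost_f * df,
    )
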