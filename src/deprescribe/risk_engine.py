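"""Per-cycle probability mathematics.

All time-scale conversions use a constant-hazard (exponential-within-band)
assumption: an annual probability p converts to a cycle of length t years
as 1 - (1-p)^t.  The treatment effect of medication reduction enters as
relative risks rescaled to the modelled systolic BP difference by
log-linear interpolation, RR^(delta/reference).  Post-event mortality and
the prior-CVD risk multiplier act on the hazard (log-survival) scale so
results stay in [0, 1].
"""

from __future__ import annotations

import numpy as np

from .cohort import PatientProfile
from .parameters import ModelParameters

__all__ = [
    "ARM_USUAL",
    "ARM_REDUCTION",
    "prob_rescale",
    "interpolate_rr",
    "effective_rrs",
    "cvd_event_prob",
    "classify_cvd_event",
    "hf_prob",
    "adverse_event_probs",
    "death_prob",
    "hf_band_index",
    "event_band_85",
]

ARM_USUAL = "usual_care"
ARM_REDUCTION = "reduction"

# integer state codes used by the simulation engine
STATE_FREE = 0
STATE_MI = 1
STATE_ACS = 2
STATE_ANGINA = 3
STATE_STROKE = 4
STATE_TIA = 5
STATE_HF = 6
STATE_FALL = 7
STATE_AKI = 8
STATE_DEAD = 9

STATE_NAMES = {
    STATE_FREE: "event-free",
    STATE_MI: "post-mi",
    STATE_ACS: "post-acs",
    STATE_ANGINA: "post-angina",
    STATE_STROKE: "post-stroke",
    STATE_TIA: "post-tia",
    STATE_HF: "post-hf",
    STATE_FALL: "post-serious-fall",
    STATE_AKI: "post-aki",
    STATE_DEAD: "dead",
}

# state code -> SMR key in MortalityModel.smr
SMR_KEYS = {
    STATE_MI: "mi",
    STATE_ACS: "acs",
    STATE_ANGINA: "angina",
    STATE_STROKE: "stroke",
    STATE_TIA: "tia",
    STATE_HF: "hf",
    STATE_FALL: "serious_fall",
    STATE_AKI: "aki",
}


def prob_rescale(p, from_years: float, to_years: float):
    """Convert a probability over ``from_years`` to one over ``to_years``
    under a constant hazard: 1 - (1-p)^(to/from).

    Accepts scalars or arrays; p = 1 maps to 1 for any durations.
    """
    if from_years <= 0 or to_years <= 0:
        raise ValueError("durations must be > 0")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probability outside [0, 1]")
    out = 1.0 - (1.0 - p) ** (to_years / from_years)
    return float(out) if out.ndim == 0 else out


def interpolate_rr(rr_ref, delta_sbp: float, reference_delta: float):
    """Rescale a relative risk quoted at ``reference_delta`` mm Hg to
    ``delta_sbp`` mm Hg: RR^(delta/reference) (log-linear in BP difference).
    """
    rr_ref = np.asarray(rr_ref, dtype=float)
    if np.any(rr_ref <= 0):
        raise ValueError("relative risk must be > 0")
    if reference_delta <= 0:
        raise ValueError("reference BP difference must be > 0")
    out = rr_ref ** (delta_sbp / reference_delta)
    return float(out) if out.ndim == 0 else out


def _effect_active(params: ModelParameters, arm: str, elapsed_years: float) -> bool:
    if arm != ARM_REDUCTION:
        return False
    dur = params.treatment_effect.effect_duration_years
    return dur is None or elapsed_years < dur


def effective_rrs(params: ModelParameters, arm: str, elapsed_years: float) -> dict[str, float]:
    """Interpolated relative risks in force at ``elapsed_years`` for ``arm``.

    Usual care — and the reduction arm once the effect duration has lapsed
    (step reversion to 1, no taper) — gets 1 for every class.
    """
    if not _effect_active(params, arm, elapsed_years):
        return {"chd": 1.0, "stroke_tia": 1.0, "hf": 1.0, "sae": 1.0, "minor": 1.0}
    te = params.treatment_effect
    d, ref = te.delta_sbp_mmhg, te.reference_delta_mmhg
    return {
        "chd": interpolate_rr(te.rr_chd, d, ref),
        "stroke_tia": interpolate_rr(te.rr_stroke_tia, d, ref),
        "hf": interpolate_rr(te.rr_hf, d, ref),
        "sae": interpolate_rr(te.rr_sae, d, ref),
        "minor": interpolate_rr(te.rr_minor, d, ref),
    }


def cvd_event_prob(
    patient: PatientProfile,
    params: ModelParameters,
    arm: str,
    elapsed_years: float = 0.0,
) -> float:
    """Per-cycle probability of a CHD or cerebrovascular event.

    The patient's 10-year CVD risk is hazard-rescaled to one cycle (prior
    CVD multiplies the hazard by the configured factor, base 1.5).  In the
    reduction arm, while the BP effect lasts, each event class is multiplied
    by its interpolated RR; because classes split 50:50 the total is the
    base probability times the mean of the two class RRs.  Capped at 1.
    """
    cl = params.simulation.cycle_length_years
    mult = params.event_risks.prior_cvd_multiplier if patient.n_prior_cvd > 0 else 1.0
    base = 1.0 - (1.0 - patient.ten_year_cvd_risk) ** (mult * cl / 10.0)
    rr = effective_rrs(params, arm, elapsed_years)
    w_chd, w_cer = params.event_risks.chd_cerebro_split
    return min(1.0, base * (w_chd * rr["chd"] + w_cer * rr["stroke_tia"]))


def event_band_85(age) -> np.ndarray:
    """Index into the event-composition age bands: 0 for 75-84, 1 for 85+."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 75):
        raise ValueError("event-type tables cover ages 75 and above only")
    out = (age >= 85).astype(int)
    return out


def classify_cvd_event(
    age: float, sex: str, params: ModelParameters, rng: np.random.Generator
) -> str:
    """Draw the event type: CHD vs cerebrovascular at the configured split,
    then the subtype from the sex-and-age-band composition table."""
    er = params.event_risks
    band = ("75-84", "85+")[int(event_band_85(age))]
    if rng.random() < er.chd_cerebro_split[0]:
        p_mi, p_acs, _ = er.chd_type_fractions[sex][band]
        u = rng.random()
        if u < p_mi:
            return "mi"
        if u < p_mi + p_acs:
            return "acs"
        return "angina"
    p_stroke, _ = er.cerebro_type_fractions[sex][band]
    return "stroke" if rng.random() < p_stroke else "tia"


def hf_prob(
    age: float, params: ModelParameters, arm: str, elapsed_years: float = 0.0
) -> float:
    """Per-cycle heart-failure probability from the age-band annual risk,
    multiplied by the interpolated HF relative risk while the effect lasts."""
    cl = params.simulation.cycle_length_years
    annual = params.event_risks.hf_annual_risk[hf_band_name(age)]
    rr = effective_rrs(params, arm, elapsed_years)["hf"]
    return min(1.0, prob_rescale(annual, 1.0, cl) * rr)


def hf_band_name(age: float) -> str:
    if age < 80:
        raise ValueError("heart-failure risk table starts at age 80")
    if age < 85:
        return "80-84"
    if age < 90:
        return "85-89"
    return "90+"


def hf_band_index(age) -> np.ndarray:
    """Vectorized band lookup: 0 for 80-84, 1 for 85-89, 2 for 90+."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 80):
        raise ValueError("heart-failure risk table starts at age 80")
    return (age >= 85).astype(int) + (age >= 90).astype(int)


def adverse_event_probs(
    params: ModelParameters, arm: str, elapsed_years: float = 0.0
) -> tuple[float, float]:
    """Per-cycle (serious, minor) antihypertensive adverse-event
    probabilities; the reduction arm multiplies both by the interpolated
    adverse-event RR while the effect lasts."""
    cl = params.simulation.cycle_length_years
    rr = effective_rrs(params, arm, elapsed_years)
    serious = min(1.0, prob_rescale(params.event_risks.sae_annual_risk, 1.0, cl) * rr["sae"])
    minor = min(1.0, prob_rescale(params.event_risks.minor_ae_annual_risk, 1.0, cl) * rr["minor"])
    return serious, minor


def death_prob(age: float, sex: str, state: int, params: ModelParameters) -> float:
    """Per-cycle background death probability.

    Life-table annual qx (non-circulatory) with the post-event state's SMR
    applied on the hazard scale: 1 - (1-qx)^(SMR * cycle_length).  Ages
    beyond the table use its terminal row.
    """
    cl = params.simulation.cycle_length_years
    qx = params.mortality.annual_qx(int(age), sex == "M")
    smr = params.mortality.smr[SMR_KEYS[state]] if state in SMR_KEYS else 1.0
    return min(1.0, 1.0 - (1.0 - qx) ** (smr * cl))
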