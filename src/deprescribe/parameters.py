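"""Model parameter set: loading, validation, and PSA distributions.

Single source of truth for every model input: the treatment effect of
withdrawing one antihypertensive (systolic BP difference and the relative
risks attached to it), event risks, life-table mortality with post-event
standardized mortality ratios (SMRs), health-state utilities, unit costs,
and the simulation configuration.

Parameters are read from a YAML document whose keys mirror the published
parameter table; anything missing is filled from the bundled base-case
defaults.  Unit costs are placeholders for an unpublished cost appendix and
are flagged ``non-paper-default`` unless the user supplies their own.

For probabilistic sensitivity analysis each uncertain parameter carries a
:class:`PSADistributionSpec`: beta for probabilities and utilities, gamma
for costs, lognormal for relative risks and SMRs.
"""

from __future__ import annotations

import copy
import dataclasses
import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterError",
    "PSADistributionSpec",
    "TreatmentEffect",
    "EventRiskSet",
    "MortalityModel",
    "UtilityModel",
    "CostModel",
    "SimulationConfig",
    "ModelParameters",
    "load_parameters",
    "load_life_table",
    "fit_distribution",
    "draw_psa_parameters",
    "get_by_path",
    "set_by_path",
]

_Z975 = 1.959963984540054  # standard normal 97.5% quantile

AGE_BANDS_EVENT = ("75-84", "85+")
AGE_BANDS_HF = ("80-84", "85-89", "90+")
EVENT_TYPES = ("mi", "acs", "angina", "stroke", "tia", "hf", "serious_fall", "aki")
MINOR_TYPES = ("hypotension", "syncope", "bradycardia", "electrolyte", "nonserious_fall")


class ParameterError(ValueError):
    """A configuration value violates the parameter schema or an invariant."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


def _check_prob(key: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(key, f"probability {value!r} outside [0, 1]")


def _check_fractions(key: str, values, n: int) -> None:
    if len(values) != n:
        raise ParameterError(key, f"expected {n} fractions, got {len(values)}")
    for v in values:
        _check_prob(key, v)
    if abs(sum(values) - 1.0) > 1e-9:
        raise ParameterError(key, f"fractions {values!r} do not sum to 1")


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSADistributionSpec:
    """Sampling distribution attached to one uncertain parameter.

    ``family`` is one of ``beta``, ``gamma``, ``lognormal`` or ``fixed``;
    ``params`` holds the family's natural parameters.
    """

    family: str
    params: dict[str, float]

    def mean(self) -> float:
        p = self.params
        if self.family == "fixed":
            return p["value"]
        if self.family == "beta":
            return p["a"] / (p["a"] + p["b"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "lognormal":
            return math.exp(p["mu"] + 0.5 * p["sigma"] ** 2)
        raise ParameterError("family", f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, size=None):
        p = self.params
        if self.family == "fixed":
            return p["value"] if size is None else np.full(size, p["value"])
        if self.family == "beta":
            return rng.beta(p["a"], p["b"], size=size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], size=size)
        raise ParameterError("family", f"unknown family {self.family!r}")

    def ppf(self, q: float) -> float:
        from scipy import stats

        p = self.params
        if self.family == "fixed":
            return p["value"]
        if self.family == "beta":
            return float(stats.beta.ppf(q, p["a"], p["b"]))
        if self.family == "gamma":
            return float(stats.gamma.ppf(q, p["shape"], scale=p["scale"]))
        if self.family == "lognormal":
            return float(stats.lognorm.ppf(q, p["sigma"], scale=math.exp(p["mu"])))
        raise ParameterError("family", f"unknown family {self.family!r}")


def fit_distribution(
    point: float,
    ci_low: float | None = None,
    ci_high: float | None = None,
    family: str = "fixed",
    se_fraction: float = 0.2,
) -> PSADistributionSpec:
    """Fit a PSA distribution to a point estimate and optional 95% CI.

    With a CI, lognormal specs match the median to the point estimate and
    derive sigma from the CI width on the log scale; beta and gamma specs
    moment-match the mean to the point estimate with SE = CI width / (2 z).
    Without a CI, SE defaults to ``se_fraction`` (20%) of the mean — a
    common convention when only a point estimate is published.
    """
    if family == "fixed":
        return PSADistributionSpec("fixed", {"value": float(point)})

    has_ci = ci_low is not None and ci_high is not None
    if has_ci and not (ci_low <= point <= ci_high):
        raise ParameterError("ci", f"CI [{ci_low}, {ci_high}] does not bracket {point}")

    if family == "lognormal":
        if point <= 0:
            raise ParameterError("point", "lognormal requires a positive point estimate")
        if has_ci:
            if ci_low <= 0:
                raise ParameterError("ci", "lognormal CI must be positive")
            sigma = (math.log(ci_high) - math.log(ci_low)) / (2.0 * _Z975)
            mu = math.log(point)  # median matches the point estimate
        else:
            se = se_fraction * point
            sigma2 = math.log(1.0 + (se / point) ** 2)
            sigma = math.sqrt(sigma2)
            mu = math.log(point) - 0.5 * sigma2  # mean matches the point estimate
        return PSADistributionSpec("lognormal", {"mu": mu, "sigma": sigma})

    se = (ci_high - ci_low) / (2.0 * _Z975) if has_ci else se_fraction * point

    if family == "beta":
        if not (0.0 < point < 1.0):
            raise ParameterError("point", f"beta requires point in (0, 1), got {point}")
        var = se**2
        nu = point * (1.0 - point) / var - 1.0
        if nu <= 0:
            raise ParameterError(
                "ci", f"beta moment match infeasible: SE {se:.4g} too large for mean {point:.4g}"
            )
        return PSADistributionSpec("beta", {"a": point * nu, "b": (1.0 - point) * nu})

    if family == "gamma":
        if point <= 0 or se <= 0:
            raise ParameterError("point", "gamma requires positive mean and SE")
        shape = (point / se) ** 2
        return PSADistributionSpec("gamma", {"shape": shape, "scale": se**2 / point})

    raise ParameterError("family", f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TreatmentEffect:
    """Effect of withdrawing one antihypertensive.

    The systolic BP rise observed under medication reduction
    (``delta_sbp_mmhg``, ITT difference at 12 weeks) converts literature
    relative risks — quoted at ``reference_delta_mmhg`` — to the modelled
    BP difference via log-linear interpolation RR^(delta/reference).
    ``effect_duration_years`` of None means the difference persists for the
    patient's lifetime.
    """

    delta_sbp_mmhg: float = 3.4
    reference_delta_mmhg: float = 3.4
    rr_chd: float = 1.009
    rr_stroke_tia: float = 1.108
    rr_hf: float = 1.290
    rr_sae: float = 0.685
    rr_minor: float = 0.685
    effect_duration_years: float | None = None
    maintain_reduction_prob: float = 0.663
    # annual utility gained under the reduced regimen (0 in the base case;
    # the utility threshold analysis searches over it)
    reduction_utility_gain_annual: float = 0.0

    def validate(self) -> None:
        for name in ("rr_chd", "rr_stroke_tia", "rr_hf", "rr_sae", "rr_minor"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"treatment_effect.{name}", "relative risk must be > 0")
        if self.reference_delta_mmhg <= 0:
            raise ParameterError(
                "treatment_effect.reference_delta_mmhg", "reference BP difference must be > 0"
            )
        _check_prob("treatment_effect.maintain_reduction_prob", self.maintain_reduction_prob)
        if self.effect_duration_years is not None and self.effect_duration_years <= 0:
            raise ParameterError(
                "treatment_effect.effect_duration_years", "duration must be > 0 or null"
            )


@dataclass
class EventRiskSet:
    """Baseline event risks and type-composition tables."""

    chd_cerebro_split: list[float] = field(default_factory=lambda: [0.5, 0.5])
    cerebro_type_fractions: dict = field(default_factory=dict)
    chd_type_fractions: dict = field(default_factory=dict)
    hf_annual_risk: dict = field(default_factory=dict)
    sae_annual_risk: float = 0.0174
    fall_aki_split: list[float] = field(default_factory=lambda: [0.52, 0.48])
    minor_ae_annual_risk: float = 0.137
    prior_cvd_multiplier: float = 1.5

    def validate(self) -> None:
        _check_fractions("event_risks.chd_cerebro_split", self.chd_cerebro_split, 2)
        _check_fractions("event_risks.fall_aki_split", self.fall_aki_split, 2)
        for sex in ("M", "F"):
            for band in AGE_BANDS_EVENT:
                _check_fractions(
                    f"event_risks.cerebro_type_fractions.{sex}.{band}",
                    self.cerebro_type_fractions[sex][band],
                    2,
                )
                _check_fractions(
                    f"event_risks.chd_type_fractions.{sex}.{band}",
                    self.chd_type_fractions[sex][band],
                    3,
                )
        for band in AGE_BANDS_HF:
            _check_prob(f"event_risks.hf_annual_risk.{band}", self.hf_annual_risk[band])
        _check_prob("event_risks.sae_annual_risk", self.sae_annual_risk)
        _check_prob("event_risks.minor_ae_annual_risk", self.minor_ae_annual_risk)
        if self.prior_cvd_multiplier <= 0:
            raise ParameterError("event_risks.prior_cvd_multiplier", "multiplier must be > 0")


@dataclass
class MortalityModel:
    """Background (non-circulatory) mortality plus post-event SMRs.

    The life table gives annual death probabilities qx with circulatory
    deaths removed, by single year of age and sex; post-event states
    multiply the corresponding hazard by the state's SMR.
    """

    life_table: pd.DataFrame = None
    smr: dict = field(default_factory=dict)

    _qx_m: np.ndarray = field(default=None, repr=False, compare=False)
    _qx_f: np.ndarray = field(default=None, repr=False, compare=False)
    _age_min: int = field(default=0, repr=False, compare=False)
    _age_max: int = field(default=0, repr=False, compare=False)

    def validate(self) -> None:
        lt = self.life_table
        if lt is None or not {"age", "sex", "qx_noncvd"}.issubset(lt.columns):
            raise ParameterError("mortality.life_table", "need columns age,sex,qx_noncvd")
        if not set(lt["sex"].unique()) <= {"M", "F"}:
            raise ParameterError("mortality.life_table", "sex must be M or F")
        if ((lt["qx_noncvd"] < 0) | (lt["qx_noncvd"] > 1)).any():
            raise ParameterError("mortality.life_table", "qx outside [0, 1]")
        for state in ("mi", "acs", "angina", "stroke", "tia", "hf", "serious_fall", "aki"):
            if state not in self.smr:
                raise ParameterError(f"mortality.smr.{state}", "missing SMR")
            if self.smr[state] < 1.0:
                raise ParameterError(f"mortality.smr.{state}", "SMR must be >= 1")
        self._build_lookup()

    def _build_lookup(self) -> None:
        lt = self.life_table
        self._age_min = int(lt["age"].min())
        self._age_max = int(lt["age"].max())
        n = self._age_max - self._age_min + 1
        for sex, attr in (("M", "_qx_m"), ("F", "_qx_f")):
            sub = lt[lt["sex"] == sex].sort_values("age")
            if len(sub) != n or list(sub["age"]) != list(range(self._age_min, self._age_max + 1)):
                raise ParameterError(
                    "mortality.life_table", f"sex {sex}: ages must cover every year once"
                )
            setattr(self, attr, sub["qx_noncvd"].to_numpy(float))

    def annual_qx(self, age, male):
        """Annual non-circulatory death probability; ages beyond the table
        use its terminal row."""
        if self._qx_m is None:
            self._build_lookup()
        idx = np.clip(np.asarray(age, dtype=int) - self._age_min, 0, self._age_max - self._age_min)
        male = np.asarray(male, dtype=bool)
        out = np.where(male, self._qx_m[idx], self._qx_f[idx])
        return out if out.ndim else float(out)


@dataclass
class UtilityModel:
    """EQ-5D utilities: baseline, multiplicative post-event state utilities,
    and additive annual decrements for transient or ongoing harms."""

    baseline_utility: float = 0.769
    state_multipliers: dict = field(default_factory=dict)
    decrements_annual: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.baseline_utility > 1.0:
            raise ParameterError("utilities.baseline", "utility index must be <= 1")
        for k, v in self.state_multipliers.items():
            if not (0.0 < v <= 1.0):
                raise ParameterError(f"utilities.multipliers.{k}", f"multiplier {v} not in (0, 1]")
        for k, v in self.decrements_annual.items():
            if v < 0:
                raise ParameterError(f"utilities.decrements_annual.{k}", "decrement must be >= 0")


@dataclass
class CostModel:
    """Unit costs (GBP 2017/18) with per-entry provenance flags."""

    consultations_per_cycle: float = 0.8
    cost_per_consultation: float = 37.0
    cost_per_drug_per_cycle: float = 9.0
    safety_visit_cost: float = 37.0
    reinstatement_visit_cost: float = 37.0
    acute_event_costs: dict = field(default_factory=dict)
    longterm_event_costs_per_cycle: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in (
            "consultations_per_cycle",
            "cost_per_consultation",
            "cost_per_drug_per_cycle",
            "safety_visit_cost",
            "reinstatement_visit_cost",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"costs.{name}", "must be >= 0")
        for table in ("acute_event_costs", "longterm_event_costs_per_cycle"):
            for k, v in getattr(self, table).items():
                if v < 0:
                    raise ParameterError(f"costs.{table}.{k}", "cost must be >= 0")


@dataclass
class SimulationConfig:
    n_patients: int = 100_000
    cycle_length_years: float = 0.25
    max_horizon_years: float = 20.0
    discount_rate_annual: float = 0.035
    half_cycle_correction: bool = True
    seed: int = 20220310
    common_random_numbers: bool = True
    wtp_thresholds: list[float] = field(default_factory=lambda: [20_000.0, 30_000.0])

    @property
    def n_cycles(self) -> int:
        return int(round(self.max_horizon_years / self.cycle_length_years))

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("simulation.n_patients", "need at least one patient")
        if not (0 < self.cycle_length_years <= self.max_horizon_years):
            raise ParameterError(
                "simulation.cycle_length_years", "need 0 < cycle length <= horizon"
            )
        if self.discount_rate_annual < 0:
            raise ParameterError("simulation.discount_rate_annual", "discount rate must be >= 0")


@dataclass
class ModelParameters:
    """The full parameter set plus PSA specs keyed by dotted parameter path."""

    treatment_effect: TreatmentEffect
    event_risks: EventRiskSet
    mortality: MortalityModel
    utilities: UtilityModel
    costs: CostModel
    simulation: SimulationConfig
    psa_specs: dict[str, PSADistributionSpec] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        self.treatment_effect.validate()
        self.event_risks.validate()
        self.mortality.validate()
        self.utilities.validate()
        self.costs.validate()
        self.simulation.validate()

    def copy(self) -> "ModelParameters":
        new = copy.deepcopy(self)
        return new

    def to_dict(self) -> dict:
        """Serialize back to the config-document structure (round-trippable)."""
        te = self.treatment_effect
        er = self.event_risks

        def _val(path: str, value: float):
            if path in self.ci:
                lo, hi = self.ci[path]
                return {"value": value, "ci": [lo, hi]}
            return value

        return {
            "treatment_effect": {
                "delta_sbp_mmhg": _val("treatment_effect.delta_sbp_mmhg", te.delta_sbp_mmhg),
                "reference_delta_mmhg": te.reference_delta_mmhg,
                "rr_chd": _val("treatment_effect.rr_chd", te.rr_chd),
                "rr_stroke_tia": _val("treatment_effect.rr_stroke_tia", te.rr_stroke_tia),
                "rr_hf": _val("treatment_effect.rr_hf", te.rr_hf),
                "rr_sae": _val("treatment_effect.rr_sae", te.rr_sae),
                "rr_minor": _val("treatment_effect.rr_minor", te.rr_minor),
                "effect_duration_years": te.effect_duration_years,
                "maintain_reduction_prob": te.maintain_reduction_prob,
                "reduction_utility_gain_annual": te.reduction_utility_gain_annual,
            },
            "event_risks": {
                "chd_cerebro_split": list(er.chd_cerebro_split),
                "cerebro_type_fractions": copy.deepcopy(er.cerebro_type_fractions),
                "chd_type_fractions": copy.deepcopy(er.chd_type_fractions),
                "hf_annual_risk": dict(er.hf_annual_risk),
                "sae_annual_risk": er.sae_annual_risk,
                "fall_aki_split": list(er.fall_aki_split),
                "minor_ae_annual_risk": er.minor_ae_annual_risk,
                "prior_cvd_multiplier": er.prior_cvd_multiplier,
            },
            "mortality": {"life_table": None, "smr": dict(self.mortality.smr)},
            "utilities": {
                "baseline": self.utilities.baseline_utility,
                "multipliers": dict(self.utilities.state_multipliers),
                "decrements_annual": dict(self.utilities.decrements_annual),
            },
            "costs": {
                "consultations_per_cycle": self.costs.consultations_per_cycle,
                "cost_per_consultation": self.costs.cost_per_consultation,
                "cost_per_drug_per_cycle": self.costs.cost_per_drug_per_cycle,
                "safety_visit_cost": self.costs.safety_visit_cost,
                "reinstatement_visit_cost": self.costs.reinstatement_visit_cost,
                "acute_event_costs": dict(self.costs.acute_event_costs),
                "longterm_event_costs_per_cycle": dict(self.costs.longterm_event_costs_per_cycle),
            },
            "simulation": {
                "n_patients": self.simulation.n_patients,
                "cycle_length_years": self.simulation.cycle_length_years,
                "max_horizon_years": self.simulation.max_horizon_years,
                "discount_rate_annual": self.simulation.discount_rate_annual,
                "half_cycle_correction": self.simulation.half_cycle_correction,
                "seed": self.simulation.seed,
                "common_random_numbers": self.simulation.common_random_numbers,
                "wtp_thresholds": list(self.simulation.wtp_thresholds),
            },
        }


# ---------------------------------------------------------------------------
# Dotted-path access (used by PSA, threshold search and scenario overrides)
# ---------------------------------------------------------------------------

def get_by_path(obj: Any, path: str):
    cur = obj
    for part in path.split("."):
        cur = cur[part] if isinstance(cur, dict) else getattr(cur, part)
    return cur


def set_by_path(obj: Any, path: str, value) -> None:
    parts = path.split(".")
    cur = obj
    for part in parts[:-1]:
        cur = cur[part] if isinstance(cur, dict) else getattr(cur, part)
    last = parts[-1]
    if isinstance(cur, dict):
        if last not in cur:
            raise ParameterError(path, "unknown parameter path")
        cur[last] = value
    else:
        if not hasattr(cur, last):
            raise ParameterError(path, "unknown parameter path")
        setattr(cur, last, value)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _bundled(name: str):
    return importlib.resources.files("deprescribe.data") / name


def load_life_table(path=None) -> pd.DataFrame:
    """Read a life-table CSV (``age,sex,qx_noncvd``).  With no path, the
    bundled synthetic approximation of England & Wales 2016–2018
    non-circulatory mortality (ages 80–110) is used."""
    if path is None:
        with importlib.resources.as_file(_bundled("lifetable_synthetic.csv")) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def _defaults_doc() -> dict:
    with importlib.resources.as_file(_bundled("base_params.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def _deep_merge(base: dict, override: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        path = f"{prefix}{key}"
        if key not in base:
            raise ParameterError(path, "unknown configuration key")
        if isinstance(base[key], dict) and isinstance(val, dict) and "value" not in val:
            out[key] = _deep_merge(base[key], val, prefix=path + ".")
        else:
            out[key] = copy.deepcopy(val)
    return out


def _point_and_ci(entry) -> tuple[float, tuple[float, float] | None]:
    if isinstance(entry, dict):
        return float(entry["value"]), (float(entry["ci"][0]), float(entry["ci"][1]))
    return float(entry), None


# uncertain parameters: (dotted path, PSA family)
def _psa_roster() -> list[tuple[str, str]]:
    roster: list[tuple[str, str]] = []
    for rr in ("rr_chd", "rr_stroke_tia", "rr_hf", "rr_sae", "rr_minor"):
        roster.append((f"treatment_effect.{rr}", "lognormal"))
    roster.append(("treatment_effect.maintain_reduction_prob", "beta"))
    for band in AGE_BANDS_HF:
        roster.append((f"event_risks.hf_annual_risk.{band}", "beta"))
    roster.append(("event_risks.sae_annual_risk", "beta"))
    roster.append(("event_risks.minor_ae_annual_risk", "beta"))
    for state in ("mi", "acs", "angina", "stroke", "tia", "hf", "serious_fall", "aki"):
        roster.append((f"mortality.smr.{state}", "lognormal"))
    roster.append(("utilities.baseline_utility", "beta"))
    for k in ("stroke", "mi", "acs", "angina", "hf", "serious_fall"):
        roster.append((f"utilities.state_multipliers.{k}", "beta"))
    for k in MINOR_TYPES + ("tia", "aki"):
        roster.append((f"utilities.decrements_annual.{k}", "beta"))
    for c in (
        "cost_per_consultation",
        "cost_per_drug_per_cycle",
        "safety_visit_cost",
        "reinstatement_visit_cost",
    ):
        roster.append((f"costs.{c}", "gamma"))
    for ev in EVENT_TYPES:
        roster.append((f"costs.acute_event_costs.{ev}", "gamma"))
        roster.append((f"costs.longterm_event_costs_per_cycle.{ev}", "gamma"))
    return roster


# hard bounds re-checked on every PSA draw, by family
_PSA_BOUNDS = {"beta": (0.0, 1.0), "gamma": (0.0, None), "lognormal": (0.0, None)}


def load_parameters(config: dict | str | None = None) -> ModelParameters:
    """Build a validated :class:`ModelParameters` from a YAML path, an
    already-parsed mapping, or (None) the bundled base case.

    Missing keys are filled from the bundled defaults; a configuration that
    omits the ``costs`` block loads successfully but warns, because the
    filled-in unit costs are placeholders rather than published values.
    """
    defaults = _defaults_doc()
    if config is None:
        doc, user_doc = defaults, {}
    else:
        if isinstance(config, str):
            with open(config) as fh:
                user_doc = yaml.safe_load(fh) or {}
        else:
            user_doc = config
        if not isinstance(user_doc, dict):
            raise ParameterError("<root>", "configuration document must be a mapping")
        doc = _deep_merge(defaults, user_doc)

    if "costs" not in user_doc and config is not None:
        warnings.warn(
            "no costs supplied: using placeholder unit costs flagged non-paper-default",
            stacklevel=2,
        )

    ci: dict[str, tuple[float, float]] = {}

    te_doc = doc["treatment_effect"]
    te_kwargs: dict[str, Any] = {}
    for name in ("delta_sbp_mmhg", "rr_chd", "rr_stroke_tia", "rr_hf", "rr_sae", "rr_minor"):
        point, bounds = _point_and_ci(te_doc[name])
        te_kwargs[name] = point
        if bounds is not None:
            ci[f"treatment_effect.{name}"] = bounds
    te = TreatmentEffect(
        reference_delta_mmhg=float(te_doc["reference_delta_mmhg"]),
        effect_duration_years=(
            None
            if te_doc["effect_duration_years"] is None
            else float(te_doc["effect_duration_years"])
        ),
        maintain_reduction_prob=float(te_doc["maintain_reduction_prob"]),
        reduction_utility_gain_annual=float(te_doc.get("reduction_utility_gain_annual", 0.0)),
        **te_kwargs,
    )

    er_doc = doc["event_risks"]
    er = EventRiskSet(
        chd_cerebro_split=[float(x) for x in er_doc["chd_cerebro_split"]],
        cerebro_type_fractions={
            s: {b: [float(x) for x in v] for b, v in bands.items()}
            for s, bands in er_doc["cerebro_type_fractions"].items()
        },
        chd_type_fractions={
            s: {b: [float(x) for x in v] for b, v in bands.items()}
            for s, bands in er_doc["chd_type_fractions"].items()
        },
        hf_annual_risk={b: float(v) for b, v in er_doc["hf_annual_risk"].items()},
        sae_annual_risk=float(er_doc["sae_annual_risk"]),
        fall_aki_split=[float(x) for x in er_doc["fall_aki_split"]],
        minor_ae_annual_risk=float(er_doc["minor_ae_annual_risk"]),
        prior_cvd_multiplier=float(er_doc["prior_cvd_multiplier"]),
    )

    mort_doc = doc["mortality"]
    mortality = MortalityModel(
        life_table=load_life_table(mort_doc.get("life_table")),
        smr={k: float(v) for k, v in mort_doc["smr"].items()},
    )

    ut_doc = doc["utilities"]
    utilities = UtilityModel(
        baseline_utility=float(ut_doc["baseline"]),
        state_multipliers={k: float(v) for k, v in ut_doc["multipliers"].items()},
        decrements_annual={k: float(v) for k, v in ut_doc["decrements_annual"].items()},
    )

    cost_doc = doc["costs"]
    user_costs = user_doc.get("costs", {})
    provenance = {}
    for key in (
        "consultations_per_cycle",
        "cost_per_consultation",
        "cost_per_drug_per_cycle",
        "safety_visit_cost",
        "reinstatement_visit_cost",
    ):
        if key == "consultations_per_cycle":
            provenance[key] = "user" if key in user_costs else "paper"
        else:
            provenance[key] = "user" if key in user_costs else "non-paper-default"
    for table in ("acute_event_costs", "longterm_event_costs_per_cycle"):
        for ev in cost_doc[table]:
            provenance[f"{table}.{ev}"] = (
                "user" if ev in user_costs.get(table, {}) else "non-paper-default"
            )
    costs = CostModel(
        consultations_per_cycle=float(cost_doc["consultations_per_cycle"]),
        cost_per_consultation=float(cost_doc["cost_per_consultation"]),
        cost_per_drug_per_cycle=float(cost_doc["cost_per_drug_per_cycle"]),
        safety_visit_cost=float(cost_doc["safety_visit_cost"]),
        reinstatement_visit_cost=float(cost_doc["reinstatement_visit_cost"]),
        acute_event_costs={k: float(v) for k, v in cost_doc["acute_event_costs"].items()},
        longterm_event_costs_per_cycle={
            k: float(v) for k, v in cost_doc["longterm_event_costs_per_cycle"].items()
        },
        provenance=provenance,
    )

    sim_doc = doc["simulation"]
    sim = SimulationConfig(
        n_patients=int(sim_doc["n_patients"]),
        cycle_length_years=float(sim_doc["cycle_length_years"]),
        max_horizon_years=float(sim_doc["max_horizon_years"]),
        discount_rate_annual=float(sim_doc["discount_rate_annual"]),
        half_cycle_correction=bool(sim_doc["half_cycle_correction"]),
        seed=int(sim_doc["seed"]),
        common_random_numbers=bool(sim_doc["common_random_numbers"]),
        wtp_thresholds=[float(x) for x in sim_doc["wtp_thresholds"]],
    )

    params = ModelParameters(
        treatment_effect=te,
        event_risks=er,
        mortality=mortality,
        utilities=utilities,
        costs=costs,
        simulation=sim,
        ci=ci,
    )
    params.validate()
    params.psa_specs = _build_psa_specs(params)
    return params


def _build_psa_specs(params: ModelParameters) -> dict[str, PSADistributionSpec]:
    specs = {}
    for path, family in _psa_roster():
        point = float(get_by_path(params, path))
        bounds = params.ci.get(path)
        if family == "beta" and not (0.0 < point < 1.0):
            # degenerate probability/utility (e.g. a decrement set to 0):
            # no sampling uncertainty can be attached, keep it fixed
            specs[path] = PSADistributionSpec("fixed", {"value": point})
            continue
        if family == "gamma" and point <= 0:
            specs[path] = PSADistributionSpec("fixed", {"value": point})
            continue
        lo, hi = (bounds if bounds is not None else (None, None))
        specs[path] = fit_distribution(point, lo, hi, family)
    return specs


def draw_psa_parameters(
    params: ModelParameters, rng: np.random.Generator, max_resample: int = 100
) -> ModelParameters:
    """Resample every uncertain parameter from its PSA spec.

    Draws violating a hard invariant (probability outside [0, 1], SMR below
    1) are redrawn up to ``max_resample`` times and then raise — draws are
    never silently truncated.  Fixed specs pass through unchanged.
    """
    new = params.copy()
    for path, spec in params.psa_specs.items():
        if spec.family == "fixed":
            continue
        lo, hi = _PSA_BOUNDS[spec.family]
        if path.startswith("mortality.smr."):
            lo = 1.0
        value = None
        for _ in range(max_resample):
            cand = float(spec.sample(rng))
            if (lo is None or cand >= lo) and (hi is None or cand <= hi):
                value = cand
                break
        if value is None:
            raise ParameterError(path, f"PSA draw violated bounds {max_resample} times")
        set_by_path(new, path, value)
    new.validate()
    return new
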