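import copy

import numpy as np
import pandas as pd
import pytest

from deprescribe import load_parameters
from deprescribe.parameters import ModelParameters


@pytest.fixture(scope="session")
def base_params() -> ModelParameters:
    return load_parameters()


@pytest.fixture()
def params(base_params) -> ModelParameters:
    """A mutable per-test copy of the base-case parameter set."""
    return copy.deepcopy(base_params)


def make_flat_lifetable(qx: float) -> pd.DataFrame:
    """Constant annual death probability at every age/sex (removes age
    dependence, so closed-form chain evaluations are exact)."""
    ages = np.arange(80, 111)
    rows = []
    for sex in ("M", "F"):
        for a in ages:
            rows.append({"age": a, "sex": sex, "qx_noncvd": qx})
    return pd.DataFrame(rows)


def uniform_cohort(n: int, **overrides) -> pd.DataFrame:
    """A cohort of n identical patients (defaults: 84-year-old male, no
    prior CVD, zero CVD risk, utility 0.769, 2 drugs, maintained)."""
    base = {
        "age": 84.0,
        "sex": "M",
        "n_prior_cvd": 0,
        "ten_year_cvd_risk": 0.0,
        "baseline_utility": 0.769,
        "frailty": "fit",
        "n_drugs": 2,
        "maintained_reduction": True,
    }
    base.update(overrides)
    return pd.DataFrame({k: [v] * n for k, v in base.items()})


def zero_hazard_params(params: ModelParameters, qx: float = 0.0) -> ModelParameters:
    """Switch off every event and death hazard (or set flat mortality qx)."""
    p = copy.deepcopy(params)
    p.event_risks.sae_annual_risk = 0.0
    p.event_risks.minor_ae_annual_risk = 0.0
    p.event_risks.hf_annual_risk = {b: 0.0 for b in p.event_risks.hf_annual_risk}
    p.mortality.life_table = make_flat_lifetable(qx)
    p.mortality.validate()
    return p
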