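import numpy as np
import pytest

from swiburden import CountryParameters, ModelConfig, calibrate


@pytest.fixture
def spain_like():
    """A country with the worked-example hospital rates (inpatient 4%,
    readmissions 1.6% of an ~5.6% total at 30 days)."""
    return CountryParameters(
        country_code="ESP",
        cabg_per_year=8294,
        sswi_incidence=4.0,
        dswi_incidence=1.6,
        readmit_prob_given_swi=0.3,
        extra_los_sswi=2.0,
        extra_los_dswi=40.0,
        icu_cost_per_day=1500.0,
        gw_cost_per_day=400.0,
        baseline_icu_los=2.0,
        baseline_gw_los=7.0,
    )


def random_country(rng: np.random.Generator, code: str = "XRR") -> CountryParameters:
    """A random valid parameter set spanning the plausible input space."""
    total = rng.uniform(2.0, 11.0)
    dswi = rng.uniform(0.2, 0.6) * total
    return CountryParameters(
        country_code=code,
        cabg_per_year=float(rng.integers(1000, 200000)),
        sswi_incidence=total - dswi,
        dswi_incidence=dswi,
        readmit_prob_given_swi=float(rng.uniform(0.0, 0.9)),
        extra_los_sswi=float(rng.uniform(1.0, 49.0)),
        extra_los_dswi=float(rng.uniform(5.0, 66.0)),
        icu_cost_per_day=float(rng.uniform(400.0, 10000.0)),
        gw_cost_per_day=float(rng.uniform(100.0, 2500.0)),
        baseline_icu_los=float(rng.uniform(1.0, 5.0)),
        baseline_gw_los=float(rng.uniform(3.0, 12.0)),
    )


def random_model(rng: np.random.Generator, horizon: int = 60):
    """A random valid transition model (country + calibrated incidence)."""
    from swiburden import build_transition_model

    params = random_country(rng)
    inc = calibrate(params.total_swi_incidence, country_code=params.country_code)
    cfg = ModelConfig(horizon=horizon, dswi_case_fatality=float(rng.uniform(0.0, 0.35)))
    return build_transition_model(params, inc, cfg), params
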