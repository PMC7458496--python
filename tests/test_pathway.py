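"""Markov pathway: transition construction, cohort engine, Monte-Carlo oracle."""

import numpy as np
import pytest

from swiburden import (
    ModelConfig,
    baseline_transition_model,
    build_transition_model,
    calibrate,
    extract_events,
    run_cohort,
    simulate_patients,
)
from swiburden.pathway import STATES, _IDX

from conftest import random_model


def _model(params, hazard_scale=1.0, **cfg_kwargs):
    inc = calibrate(params.total_swi_incidence, country_code=params.country_code)
    return build_transition_model(params, inc, ModelConfig(**cfg_kwargs), hazard_scale)


def test_geometric_dwell_inversion(spain_like):
    """Mean GW stay of 5 days -> self-loop 0.8 / exit 0.2 in the baseline."""
    p = spain_like
    p.baseline_gw_los = 5.0
    model = _model(p, hazard_scale=0.0)
    gw = _IDX["GW"]
    assert model.matrices[0, gw, gw] == pytest.approx(0.8)
    assert model.matrices[0, gw, _IDX["HOME"]] == pytest.approx(0.2)


def test_rows_sum_to_one_for_all_states_and_cycles(spain_like):
    model = _model(spain_like)
    rowsums = model.matrices.sum(axis=2)
    assert np.allclose(rowsums, 1.0, atol=1e-12, rtol=0.0)


def test_zero_hazard_reduces_to_baseline_pathway(spain_like):
    model = _model(spain_like, hazard_scale=0.0)
    trace = run_cohort(model, volume=1000.0)
    assert trace.swi_events == 0.0
    assert trace.readmissions == 0.0
    assert trace.deaths == 0.0
    # truncated-geometric mean stay: horizon 90 >> LOS, so within 1%
    assert trace.icu_days == pytest.approx(1000.0 * spain_like.baseline_icu_los, rel=0.01)
    assert trace.gw_days == pytest.approx(1000.0 * spain_like.baseline_gw_los, rel=0.01)


def test_cohort_occupancy_conserved_and_volume_linear(spain_like):
    model = _model(spain_like)
    t1 = run_cohort(model, volume=1.0)
    t2 = run_cohort(model, volume=2.0)
    assert np.allclose(t1.occupancy.sum(axis=1), 1.0, atol=1e-9)
    for fld in ("icu_days", "gw_days", "sswi_events", "dswi_events", "readmissions", "deaths"):
        assert getattr(t2, fld) == pytest.approx(2.0 * getattr(t1, fld), abs=1e-12)
    t0 = run_cohort(model, volume=0.0)
    assert t0.swi_events == t0.icu_days == t0.gw_days == 0.0


def test_event_split_identity(spain_like):
    trace = run_cohort(_model(spain_like), volume=1.0)
    assert trace.sswi_events + trace.dswi_events == pytest.approx(
        trace.inpatient_swi_events + trace.postdischarge_swi_events, abs=1e-12
    )


def test_worked_example_rate_addition():
    """Hospital SWI rate is inpatient rate plus readmission rate (4% + 1.6%)."""
    from swiburden.pathway import EventSummary

    ev = EventSummary(
        swi_events=56.0, inpatient_rate=0.04, readmission_rate=0.016,
        excess_icu_days=0.0, excess_gw_days=0.0, readmit_days=0.0,
        readmissions=16.0, deaths=0.0, volume=1000.0,
    )
    assert ev.r_swi == pytest.approx(0.056)


def test_extract_events_zero_hazard_means_zero_excess(spain_like):
    base = _model(spain_like, hazard_scale=0.0)
    trace = run_cohort(base, 500.0)
    ev = extract_events(trace, run_cohort(base, 500.0))
    assert ev.excess_icu_days == pytest.approx(0.0, abs=1e-9)
    assert ev.excess_gw_days == pytest.approx(0.0, abs=1e-9)
    assert ev.r_swi == 0.0


def test_extract_events_rejects_mismatched_traces(spain_like):
    m60 = _model(spain_like, horizon=60)
    m90 = _model(spain_like, horizon=90)
    with pytest.raises(ValueError):
        extract_events(run_cohort(m60, 1.0), run_cohort(m90, 1.0))


def test_known_extra_los_yields_matching_excess_days(spain_like):
    """Superficial-only SWIs with 10-day extra LOS add ~10 GW days each."""
    p = spain_like
    p.dswi_incidence = 0.0
    p.sswi_incidence = 5.6
    p.extra_los_sswi = 10.0
    p.readmit_prob_given_swi = 1.0  # every post-discharge SWI is readmitted
    model = _model(p)
    base = _model(p, hazard_scale=0.0)
    trace = run_cohort(model, 1.0)
    ev = extract_events(trace, run_cohort(base, 1.0))
    per_event_gw = (ev.excess_gw_days + ev.readmit_days) / trace.swi_events
    # each SWI adds its 10 care days plus (readmitted cases) one admission day,
    # less late-horizon truncation
    assert 9.5 < per_event_gw < 11.5


def test_monotone_in_hazard_scale(spain_like):
    inc = calibrate(spain_like.total_swi_incidence)
    cfg = ModelConfig()
    prev_events, prev_days = -1.0, -1.0
    for scale in (0.0, 0.5, 1.0, 1.5):
        m = build_transition_model(spain_like, inc, cfg, hazard_scale=scale)
        tr = run_cohort(m, 1.0)
        assert tr.swi_events >= prev_events
        assert tr.gw_days + tr.icu_days >= prev_days - 1e-12
        prev_events, prev_days = tr.swi_events, tr.gw_days + tr.icu_days


def test_burden_vanishes_as_extra_los_and_readmission_vanish(spain_like):
    p = spain_like
    p.extra_los_sswi = 1e-6
    p.extra_los_dswi = 1e-6
    p.readmit_prob_given_swi = 0.0
    model = _model(p, dswi_case_fatality=0.0)
    base = _model(p, hazard_scale=0.0, dswi_case_fatality=0.0)
    ev = extract_events(run_cohort(model, 1.0), run_cohort(base, 1.0))
    # SWI care collapses to <= 1-day stays; remaining excess is only the
    # displaced baseline occupancy of infected patients
    assert ev.readmit_days == 0.0
    assert ev.excess_icu_days + ev.excess_gw_days < 0.2


def test_simulation_is_seed_deterministic(spain_like):
    model = _model(spain_like)
    a = simulate_patients(model, 500, seed=42)
    b = simulate_patients(model, 500, seed=42)
    assert np.array_equal(a.occupancy, b.occupancy)
    assert a.swi_events == b.swi_events and a.icu_days == b.icu_days


def test_monte_carlo_oracle_matches_cohort(spain_like):
    """Patient-level simulation agrees with the deterministic cohort engine."""
    model = _model(spain_like)
    n = 20000
    cohort = run_cohort(model, 1.0)
    mc = simulate_patients(model, n, seed=7)
    for fld, bernoulli in (
        ("swi_events", True), ("readmissions", True), ("deaths", True),
        ("icu_days", False), ("gw_days", False),
    ):
        cohort_mean = getattr(cohort, fld)
        mc_mean = getattr(mc, fld) / n
        if bernoulli:
            se = np.sqrt(max(cohort_mean * (1 - cohort_mean), 1e-12) / n)
        else:
            se = max(cohort_mean, 0.5) / np.sqrt(n)  # conservative scale bound
        assert abs(mc_mean - cohort_mean) < 4 * se + 1e-9, fld


def test_invalid_parameter_named_in_error(spain_like):
    inc = calibrate(spain_like.total_swi_incidence)
    spain_like.extra_los_dswi = 0.0
    # zero-day care is allowed (exit after one cycle); negative is not
    spain_like.extra_los_dswi = -1.0
    with pytest.raises(ValueError):
        build_transition_model(spain_like, inc)


def test_dead_state_is_absorbing(spain_like):
    model = _model(spain_like, dswi_case_fatality=0.3)
    dead = _IDX["DEAD"]
    assert np.all(model.matrices[:, dead, dead] == 1.0)
    trace = run_cohort(model, 1.0)
    assert trace.deaths > 0
    assert np.all(np.diff(trace.occupancy[:, dead]) >= -1e-15)
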