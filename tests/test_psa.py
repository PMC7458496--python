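"""Probabilistic sensitivity analysis: sampling, pipeline reruns, summaries."""

import numpy as np
import pandas as pd
import pytest

from swiburden import PSAConfig, run_psa, sample_parameters, summarize
from swiburden.psa import draws_to_frame


def test_zero_spread_reproduces_point_estimates(spain_like):
    cfg = PSAConfig(iterations=2, seed=1, default_sd_frac=0.0)
    drawn = sample_parameters(spain_like, cfg, draw_index=0)
    for f in ("icu_cost_per_day", "sswi_incidence", "extra_los_dswi"):
        assert getattr(drawn, f) == getattr(spain_like, f)


def test_same_seed_and_index_identical_draw(spain_like):
    cfg = PSAConfig(iterations=5, seed=9)
    a = sample_parameters(spain_like, cfg, draw_index=3)
    b = sample_parameters(spain_like, cfg, draw_index=3)
    c = sample_parameters(spain_like, cfg, draw_index=4)
    assert a == b
    assert a != c


def test_field_substreams_are_independent(spain_like):
    """Pinning one field's spread to zero does not perturb other fields."""
    free = PSAConfig(iterations=2, seed=5)
    pinned = PSAConfig(iterations=2, seed=5, spreads={"icu_cost_per_day": 0.0})
    a = sample_parameters(spain_like, free, 0)
    b = sample_parameters(spain_like, pinned, 0)
    assert b.icu_cost_per_day == spain_like.icu_cost_per_day
    assert a.gw_cost_per_day == b.gw_cost_per_day
    assert a.sswi_incidence == b.sswi_incidence


def test_beta_draws_match_stated_mean(spain_like):
    """readmit_prob draws are beta with mean equal to the point estimate."""
    cfg = PSAConfig(iterations=2, seed=17)
    mu = spain_like.readmit_prob_given_swi
    draws = np.array(
        [sample_parameters(spain_like, cfg, i).readmit_prob_given_swi for i in range(4000)]
    )
    sd = draws.std(ddof=1)
    assert abs(draws.mean() - mu) < 3 * sd / np.sqrt(draws.size)
    assert np.all((draws > 0) & (draws < 1))


def test_gamma_draws_match_stated_moments(spain_like):
    cfg = PSAConfig(iterations=2, seed=23)
    mu = spain_like.icu_cost_per_day
    draws = np.array(
        [sample_parameters(spain_like, cfg, i).icu_cost_per_day for i in range(4000)]
    )
    assert abs(draws.mean() - mu) < 3 * draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.std(ddof=1) / mu - cfg.default_sd_frac) < 0.02
    assert np.all(draws > 0)


def test_imputed_field_uses_stored_iqr_as_central_interval(spain_like):
    spain_like.provenance["gw_cost_per_day"] = "imputed"
    iqr = {"gw_cost_per_day": (300.0, 500.0)}
    cfg = PSAConfig(iterations=2, seed=31)
    draws = np.array(
        [sample_parameters(spain_like, cfg, i, uncertainty=iqr).gw_cost_per_day
         for i in range(3000)]
    )
    inside = np.mean((draws >= 300.0) & (draws <= 500.0))
    assert 0.4 < inside < 0.6  # IQR is the central ~50% interval


def test_run_psa_default_iterations_and_reproducibility(spain_like):
    cfg = PSAConfig(seed=4)
    draws = run_psa(spain_like, cfg)
    assert len(draws) == 52
    again = run_psa(spain_like, cfg)
    pd.testing.assert_frame_equal(draws_to_frame(draws), draws_to_frame(again))
    s1, s2 = summarize(draws), summarize(again)
    assert s1 == s2  # bit-identical summaries


def test_run_psa_zero_spread_equals_base_case(spain_like):
    from swiburden import run_country_base_case

    cfg = PSAConfig(iterations=3, seed=1, default_sd_frac=0.0)
    draws = run_psa(spain_like, cfg)
    base, _ = run_country_base_case(spain_like)
    for d in draws:
        assert d.total_cost == pytest.approx(base.total_cost, rel=1e-12)
        assert d.cost_per_swi == pytest.approx(base.cost_per_swi, rel=1e-12)


def test_base_case_within_draw_range(spain_like):
    from swiburden import run_country_base_case

    base, _ = run_country_base_case(spain_like)
    draws = draws_to_frame(run_psa(spain_like, PSAConfig(iterations=52, seed=2)))
    assert draws["total_cost"].min() <= base.total_cost <= draws["total_cost"].max()


def test_summarize_order_statistics_and_sd():
    frame = pd.DataFrame({"metric": np.arange(1.0, 53.0)})
    s = summarize(frame)
    m = s.metrics["metric"]
    assert m["median"] == 26.5
    assert (m["min"], m["max"]) == (1.0, 52.0)
    assert m["min"] <= m["iqr_low"] <= m["median"] <= m["iqr_high"] <= m["max"]
    # two-pass SD oracle
    arr = frame["metric"].to_numpy()
    mean = arr.sum() / arr.size
    sd = np.sqrt(((arr - mean) ** 2).sum() / (arr.size - 1))
    assert m["sd"] == pytest.approx(sd, abs=1e-12)
    const = summarize(pd.DataFrame({"metric": np.full(10, 3.0)}))
    assert const.metrics["metric"]["sd"] == 0.0


def test_monetary_scaling_of_cost_spreads(spain_like):
    """Scaling both cost centers by k scales monetary summaries by k at fixed seed."""
    from dataclasses import replace

    cfg = PSAConfig(iterations=20, seed=6)
    k = 2.5
    scaled = replace(
        spain_like,
        icu_cost_per_day=spain_like.icu_cost_per_day * k,
        gw_cost_per_day=spain_like.gw_cost_per_day * k,
        provenance=dict(spain_like.provenance),
    )
    a = draws_to_frame(run_psa(spain_like, cfg))
    b = draws_to_frame(run_psa(scaled, cfg))
    # same relative gamma spread and identical substreams -> exact scaling
    assert np.allclose(b["total_cost"], k * a["total_cost"], rtol=1e-9)
    assert np.allclose(b["icu_days"], a["icu_days"], rtol=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        PSAConfig(iterations=1)
    with pytest.raises(ValueError):
        PSAConfig(spreads={"not_a_field": 1.0})
    with pytest.raises(ValueError):
        PSAConfig(spreads={"icu_cost_per_day": -1.0})
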