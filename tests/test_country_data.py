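"""Country table loading, study merging, inclusion filtering and imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swiburden import (
    CANONICAL_FIELDS,
    CountryParameters,
    ParameterObservation,
    convert_currency,
    filter_included_countries,
    impute_missing,
    merge_study_values,
)
from swiburden.country_data import (
    observations_to_table,
    read_country_table,
    table_to_parameters,
    write_country_table,
)
from swiburden.synthetic_data import SyntheticSpec, generate_country_table


def _obs(values, field="extra_los_sswi", cc="FRA"):
    return [ParameterObservation(cc, field, v, f"study{i}") for i, v in enumerate(values)]


@pytest.mark.parametrize(
    "values, expected, prov",
    [
        ([10.0], 10.0, "observed"),
        ([10.0, 20.0], 15.0, "midpoint"),
        ([8.0, 20.0, 14.0], 14.0, "midpoint"),  # (min + max) / 2 spans the range
    ],
)
def test_merge_study_values(values, expected, prov):
    value, provenance = merge_study_values(_obs(values))
    assert value == pytest.approx(expected)
    assert provenance == prov


def test_merge_rejects_empty_and_mixed_keys():
    with pytest.raises(ValueError):
        merge_study_values([])
    with pytest.raises(ValueError):
        merge_study_values(_obs([1.0]) + _obs([2.0], cc="DEU"))


@given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=2, max_size=8))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_merge_midpoint_spans_range(values):
    value, _ = merge_study_values(_obs(values))
    assert value == pytest.approx((min(values) + max(values)) / 2.0)
    assert min(values) <= value <= max(values)


def _table_with_counts(counts):
    """One row per entry of ``counts``; row i has counts[i] observed fields."""
    rows = []
    for i, k in enumerate(counts):
        row = {"country_code": f"C{i:02d}"}
        for f in CANONICAL_FIELDS[:k]:
            row[f] = 1.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["country_code", *CANONICAL_FIELDS])


@pytest.mark.parametrize("n_observed, included", [(10, True), (5, True), (4, False), (0, False)])
def test_inclusion_threshold_is_at_least_five(n_observed, included):
    table = _table_with_counts([n_observed])
    kept, report = filter_included_countries(table)
    assert (len(kept) == 1) is included
    assert report.loc[0, "n_observed"] == n_observed
    assert bool(report.loc[0, "included"]) is included


def test_filter_is_idempotent():
    table = _table_with_counts([10, 7, 5, 4, 2])
    once, _ = filter_included_countries(table)
    twice, _ = filter_included_countries(once)
    pd.testing.assert_frame_equal(once, twice)


def test_impute_uses_cross_country_median_and_type7_iqr():
    table = _table_with_counts([10, 10, 10, 10, 10])
    table.loc[:3, "gw_cost_per_day"] = [1.0, 2.0, 3.0, 4.0]
    table.loc[4, "gw_cost_per_day"] = np.nan
    completed, iqr = impute_missing(table)
    assert completed.loc[4, "gw_cost_per_day"] == pytest.approx(2.5)
    assert iqr["gw_cost_per_day"] == pytest.approx((1.75, 3.25))
    assert completed.loc[4, "gw_cost_per_day__prov"] == "imputed"
    # single observed value -> degenerate IQR
    table2 = _table_with_counts([10, 9])
    completed2, iqr2 = impute_missing(table2)
    missing_field = CANONICAL_FIELDS[9]
    assert completed2[missing_field].notna().all()
    lo, hi = iqr2[missing_field]
    assert lo == hi == 1.0


def test_impute_never_alters_observed_cells_and_stays_in_range():
    spec = SyntheticSpec(n_countries=10, seed=11, missingness=0.25)
    table, _ = generate_country_table(spec)
    kept, _ = filter_included_countries(table)
    completed, _ = impute_missing(kept)
    for f in CANONICAL_FIELDS:
        observed = kept[f].dropna()
        pd.testing.assert_series_equal(
            completed.loc[observed.index, f], observed, check_names=False
        )
        assert completed[f].between(observed.min(), observed.max()).all()


def test_impute_errors_when_field_never_observed():
    table = _table_with_counts([9, 9])  # last canonical field observed nowhere
    with pytest.raises(ValueError, match=CANONICAL_FIELDS[-1]):
        impute_missing(table)


def test_impute_complete_table_is_identity():
    table = _table_with_counts([10, 10])
    completed, _ = impute_missing(table)
    pd.testing.assert_frame_equal(completed[list(table.columns)], table)


@pytest.mark.parametrize(
    "amount, rate, expected", [(100.0, 1.0, 100.0), (110.0, 1.1, 100.0), (54180.0 * 112, 112, 54180.0)]
)
def test_convert_currency(amount, rate, expected):
    assert convert_currency(amount, rate) == pytest.approx(expected)
    with pytest.raises(ValueError):
        convert_currency(amount, 0.0)


def test_country_table_roundtrip_preserves_values_and_provenance(tmp_path):
    obs = []
    for f in CANONICAL_FIELDS:
        obs.append(ParameterObservation("FRA", f, 5.0 if "incidence" not in f else 2.0))
        if f == "icu_cost_per_day":
            obs.append(ParameterObservation("FRA", f, 7.0, "second study"))
    obs[3] = ParameterObservation("FRA", "readmit_prob_given_swi", 0.3)
    table = observations_to_table(obs)
    path = tmp_path / "countries.csv"
    write_country_table(table, path, ["provenance header"])
    back = read_country_table(path)
    pd.testing.assert_frame_equal(back, table)
    assert back.loc[0, "icu_cost_per_day"] == pytest.approx(6.0)
    assert back.loc[0, "icu_cost_per_day__prov"] == "midpoint"
    params = table_to_parameters(back)[0]
    assert params.provenance["icu_cost_per_day"] == "midpoint"
    assert params.provenance["extra_los_sswi"] == "observed"


@pytest.mark.parametrize(
    "overrides",
    [
        {"cabg_per_year": 0},
        {"sswi_incidence": -1.0},
        {"sswi_incidence": 60.0, "dswi_incidence": 50.0},
        {"readmit_prob_given_swi": 1.5},
        {"icu_cost_per_day": -5.0},
        {"country_code": "FRANCE"},
    ],
)
def test_parameter_invariants_rejected(overrides):
    base = dict(
        country_code="FRA", cabg_per_year=1000, sswi_incidence=3.0, dswi_incidence=1.0,
        readmit_prob_given_swi=0.3, extra_los_sswi=5.0, extra_los_dswi=20.0,
        icu_cost_per_day=1000.0, gw_cost_per_day=300.0, baseline_icu_los=2.0,
        baseline_gw_los=6.0,
    )
    base.update(overrides)
    with pytest.raises(ValueError):
        CountryParameters(**base)
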