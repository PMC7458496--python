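"""Country-level parameter tables: loading, validation, merging, imputation.

Every downstream stage of the burden model is driven by a per-country table of
ten epidemiological and cost parameters (all monetary values in 2017 US$):

* ``cabg_per_year`` — annual CABG procedure volume,
* ``sswi_incidence`` / ``dswi_incidence`` — superficial and deep sternal-wound
  infection incidence, percent of CABG procedures,
* ``readmit_prob_given_swi`` — probability a post-discharge SWI leads to
  readmission, fraction in [0, 1],
* ``extra_los_sswi`` / ``extra_los_dswi`` — SWI-attributable additional length
  of stay, days,
* ``icu_cost_per_day`` / ``gw_cost_per_day`` — daily cost of intensive-care
  and general-ward beds,
* ``baseline_icu_los`` / ``baseline_gw_los`` — uncomplicated post-CABG stays.

Values extracted from multiple studies for the same country are merged to the
midpoint of their range.  Countries with at least five of the ten parameters
observed are retained; remaining gaps are filled with the cross-country median,
and the cross-country interquartile range (IQR) is kept as that cell's
uncertainty range for probabilistic sensitivity analysis.  Quartiles use
linear interpolation between order statistics (numpy's default, "type 7").

Provenance is tracked per cell: ``observed`` (single study), ``midpoint``
(merged from several studies) or ``imputed`` (median-filled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_FIELDS",
    "CountryParameters",
    "ParameterObservation",
    "merge_study_values",
    "filter_included_countries",
    "impute_missing",
    "convert_currency",
    "read_country_table",
    "write_country_table",
    "read_observations",
    "observations_to_table",
    "table_to_parameters",
    "load_rate_table",
]

#: The ten country-specific model parameters.  ``country_code`` is an
#: identifier and ``cabg_per_100k`` an alternative entry route for volume
#: (converted to ``cabg_per_year`` via a supplied population); neither counts
#: toward the inclusion threshold.
CANONICAL_FIELDS: tuple[str, ...] = (
    "cabg_per_year",
    "sswi_incidence",
    "dswi_incidence",
    "readmit_prob_given_swi",
    "extra_los_sswi",
    "extra_los_dswi",
    "icu_cost_per_day",
    "gw_cost_per_day",
    "baseline_icu_los",
    "baseline_gw_los",
)

#: Minimum number of observed canonical parameters for a country to enter
#: the model.
MIN_OBSERVED_FIELDS: int = 5

PROVENANCE_LEVELS = ("observed", "midpoint", "imputed")

_PROV_SUFFIX = "__prov"


@dataclass
class CountryParameters:
    """One country's complete parameter set with per-field provenance."""

    country_code: str
    cabg_per_year: float
    sswi_incidence: float
    dswi_incidence: float
    readmit_prob_given_swi: float
    extra_los_sswi: float
    extra_los_dswi: float
    icu_cost_per_day: float
    gw_cost_per_day: float
    baseline_icu_los: float
    baseline_gw_los: float
    cabg_per_100k: float | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (isinstance(self.country_code, str) and len(self.country_code) == 3):
            raise ValueError(f"country_code must be an ISO-3 string, got {self.country_code!r}")
        if not self.cabg_per_year >= 1:
            raise ValueError(f"cabg_per_year must be >= 1, got {self.cabg_per_year}")
        for name in ("sswi_incidence", "dswi_incidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percent in [0, 100], got {v}")
        if self.sswi_incidence + self.dswi_incidence > 100.0:
            raise ValueError("sswi_incidence + dswi_incidence exceeds 100%")
        if not 0.0 <= self.readmit_prob_given_swi <= 1.0:
            raise ValueError(
                f"readmit_prob_given_swi must be in [0, 1], got {self.readmit_prob_given_swi}"
            )
        for name in (
            "extra_los_sswi",
            "extra_los_dswi",
            "icu_cost_per_day",
            "gw_cost_per_day",
            "baseline_icu_los",
            "baseline_gw_los",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for fname, prov in self.provenance.items():
            if fname not in CANONICAL_FIELDS:
                raise ValueError(f"provenance refers to unknown field {fname!r}")
            if prov not in PROVENANCE_LEVELS:
                raise ValueError(f"unknown provenance level {prov!r} for {fname!r}")

    @property
    def total_swi_incidence(self) -> float:
        """Total SWI incidence, percent of CABG procedures."""
        return self.sswi_incidence + self.dswi_incidence

    @property
    def dswi_share(self) -> float:
        """Deep-SWI fraction of all SWIs (0 if incidence is zero)."""
        total = self.total_swi_incidence
        return self.dswi_incidence / total if total > 0 else 0.0


@dataclass(frozen=True)
class ParameterObservation:
    """A single raw extraction row: one study's value for one country/field."""

    country_code: str
    field_name: str
    value: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.field_name not in CANONICAL_FIELDS and self.field_name != "cabg_per_100k":
            raise ValueError(f"unknown field_name {self.field_name!r}")
        if not math.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value}")


def merge_study_values(observations: Iterable[ParameterObservation]) -> tuple[float, str]:
    """Collapse one country/field's study values to a single point estimate.

    A single study passes through unchanged (provenance ``observed``).  When
    several studies report the same quantity, the midpoint of the reported
    range, ``(min + max) / 2``, is used (provenance ``midpoint``).

    Returns ``(value, provenance)``.  Raises ``ValueError`` on an empty list
    (the missing-value case is handled by imputation) or on mixed
    country/field keys.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no observations to merge (missing value: handle via imputation)")
    keys = {(o.country_code, o.field_name) for o in obs}
    if len(keys) != 1:
        raise ValueError(f"observations mix countries/fields: {sorted(keys)}")
    if len(obs) == 1:
        return obs[0].value, "observed"
    values = [o.value for o in obs]
    return (min(values) + max(values)) / 2.0, "midpoint"


def filter_included_countries(
    table: pd.DataFrame, min_observed: int = MIN_OBSERVED_FIELDS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion rule: keep countries with >= ``min_observed`` of the
    ten canonical parameters present.

    Returns ``(included, report)`` where ``report`` has one row per country
    with its observed-field count and inclusion flag.  Idempotent: applying
    the filter to its own output changes nothing.
    """
    _require_columns(table, ("country_code",))
    present = [f for f in CANONICAL_FIELDS if f in table.columns]
    counts = table[present].notna().sum(axis=1) if present else pd.Series(0, index=table.index)
    report = pd.DataFrame(
        {
            "country_code": table["country_code"].to_numpy(),
            "n_observed": counts.to_numpy(dtype=int),
            "included": (counts >= min_observed).to_numpy(),
        }
    )
    included = table.loc[report["included"].to_numpy()].reset_index(drop=True)
    return included, report


def impute_missing(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Fill missing cells with the cross-country median of each field.

    The filled table carries provenance columns (``<field>__prov``) marking
    each imputed cell, and the function returns the cross-country IQR per
    field as ``{field: (q1, q3)}`` — the uncertainty range attached to imputed
    cells for probabilistic sensitivity analysis.  Observed cells are never
    altered.  A field observed in zero countries raises ``ValueError``.
    """
    _require_columns(table, ("country_code",))
    out = table.copy()
    iqr: dict[str, tuple[float, float]] = {}
    for fname in CANONICAL_FIELDS:
        if fname not in out.columns:
            raise ValueError(f"field {fname!r} absent from table; observed in zero countries")
        out[fname] = out[fname].astype(float)
        col = out[fname]
        observed = col.dropna().to_numpy(dtype=float)
        if observed.size == 0:
            raise ValueError(f"field {fname!r} observed in zero countries; cannot impute")
        q1, med, q3 = np.percentile(observed, [25.0, 50.0, 75.0])  # type 7 quartiles
        iqr[fname] = (float(q1), float(q3))
        prov_col = fname + _PROV_SUFFIX
        if prov_col not in out.columns:
            out[prov_col] = "observed"
        missing = col.isna()
        out.loc[missing, fname] = float(med)
        out.loc[missing, prov_col] = "imputed"
    return out, iqr


def convert_currency(amount: float, rate: float) -> float:
    """Convert a local-currency amount to 2017 US$ at a mid-2017 market rate
    expressed as local units per USD."""
    if not rate > 0:
        raise ValueError(f"exchange rate must be positive, got {rate}")
    return amount / rate


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_country_table(path: str | Path) -> pd.DataFrame:
    """Read a wide country table (one row per country, empty cells = missing).

    Lines starting with ``#`` are treated as provenance headers and skipped.
    """
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ("country_code",))
    return df


def write_country_table(table: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write a country table as CSV, with optional ``#``-prefixed header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False)


def read_observations(path: str | Path) -> list[ParameterObservation]:
    """Read a long-format observations CSV: country_code,field_name,value,source_id."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ("country_code", "field_name", "value"))
    if "source_id" not in df.columns:
        df["source_id"] = ""
    return [
        ParameterObservation(r.country_code, r.field_name, float(r.value), str(r.source_id))
        for r in df.itertuples(index=False)
    ]


def observations_to_table(observations: Iterable[ParameterObservation]) -> pd.DataFrame:
    """Merge raw per-study observations into a wide country table with
    provenance columns, applying the midpoint rule per country/field."""
    groups: dict[tuple[str, str], list[ParameterObservation]] = {}
    for o in observations:
        groups.setdefault((o.country_code, o.field_name), []).append(o)
    rows: dict[str, dict[str, object]] = {}
    for (cc, fname), obs in sorted(groups.items()):
        value, prov = merge_study_values(obs)
        row = rows.setdefault(cc, {"country_code": cc})
        row[fname] = value
        row[fname + _PROV_SUFFIX] = prov
    df = pd.DataFrame(list(rows.values()))
    cols = ["country_code"]
    for fname in CANONICAL_FIELDS + ("cabg_per_100k",):
        if fname in df.columns:
            cols += [fname, fname + _PROV_SUFFIX]
    return df[cols]


def table_to_parameters(table: pd.DataFrame) -> list[CountryParameters]:
    """Build validated :class:`CountryParameters` from a completed table."""
    out = []
    for r in table.to_dict("records"):
        provenance = {
            f: str(r[f + _PROV_SUFFIX])
            for f in CANONICAL_FIELDS
            if f + _PROV_SUFFIX in r and isinstance(r.get(f + _PROV_SUFFIX), str)
        }
        kwargs = {f: float(r[f]) for f in CANONICAL_FIELDS}
        cabg_100k = r.get("cabg_per_100k")
        out.append(
            CountryParameters(
                country_code=str(r["country_code"]),
                cabg_per_100k=float(cabg_100k) if cabg_100k is not None and not pd.isna(cabg_100k) else None,
                provenance=provenance,
                **kwargs,
            )
        )
    return out


def load_rate_table(path: str | Path) -> Mapping[str, float]:
    """Read ``rates.csv`` (currency,local_per_usd_2017) into a dict."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ("currency", "local_per_usd_2017"))
    rates = dict(zip(df["currency"].astype(str), df["local_per_usd_2017"].astype(float)))
    for cur, rate in rates.items():
        if not rate > 0:
            raise ValueError(f"exchange rate for {cur} must be positive, got {rate}")
    return rates


def _require_columns(df: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")
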