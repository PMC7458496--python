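"""Synthetic country tables and incidence observations for end-to-end testing.

The real per-country inputs behind this model come from a literature review
whose extraction table is not publicly deposited.  This module generates
tables with the same structure and the published plausible ranges, so every
downstream stage can be exercised and scored against a known ground truth:

* CABG volume: 6.4–61.4 procedures per 100 000 population (the published
  national extremes), times a population drawn log-uniformly between 5 and
  330 million;
* total SWI incidence 2.8–10.4% of procedures, deep-SWI incidence 0.8–3.4%
  (capped below the total);
* additional length of stay 2–49 days (superficial; deep up to 66 days);
* daily bed costs spanning roughly Brazil-like to Japan-like magnitudes,
  drawn log-uniformly (costs vary over an order of magnitude across systems).

Non-cost fields are uniform within their ranges — the least-assuming
emulation when only extremes are published.  Missingness is applied after
generation (never to ``country_code``), so imputation can be scored against
the stored ground truth.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .country_data import CANONICAL_FIELDS
from .incidence import HillCurveParams, hill_cumulative

__all__ = ["FIELD_RANGES", "SyntheticSpec", "generate_country_table", "generate_incidence_observations"]

#: Plausible (low, high) ranges per generated quantity.  ``log`` marks
#: log-uniform sampling.
FIELD_RANGES: dict[str, tuple[float, float, bool]] = {
    "cabg_per_100k": (6.4, 61.4, False),
    "population": (5e6, 3.3e8, True),
    "total_swi_incidence": (2.8, 10.4, False),
    "dswi_incidence": (0.8, 3.4, False),
    "readmit_prob_given_swi": (0.1, 0.5, False),
    "extra_los_sswi": (2.0, 49.0, False),
    "extra_los_dswi": (14.0, 66.0, False),
    "icu_cost_per_day": (800.0, 8000.0, True),
    "gw_cost_per_day": (150.0, 2500.0, True),
    "baseline_icu_los": (1.0, 4.0, False),
    "baseline_gw_los": (4.0, 10.0, False),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of the synthetic country-table generator."""

    n_countries: int = 14
    seed: int = 0
    missingness: Mapping[str, float] | float = 0.0
    ranges: Mapping[str, tuple[float, float, bool]] = field(default_factory=lambda: dict(FIELD_RANGES))

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError(f"n_countries must be >= 1, got {self.n_countries}")
        for fname, (lo, hi, _) in self.ranges.items():
            if not lo <= hi:
                raise ValueError(f"range for {fname!r} is not ordered: ({lo}, {hi})")
        for fname in CANONICAL_FIELDS:
            p = self.missing_prob(fname)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"missingness for {fname!r} must be in [0, 1), got {p}")

    def missing_prob(self, fname: str) -> float:
        if isinstance(self.missingness, Mapping):
            return float(self.missingness.get(fname, 0.0))
        return float(self.missingness)


def _synthetic_code(i: int) -> str:
    """Deterministic ISO-3-shaped synthetic country codes: XAA, XAB, ..."""
    return "X" + chr(ord("A") + i // 26) + chr(ord("A") + i % 26)


def _draw(rng: np.random.Generator, lo: float, hi: float, log: bool) -> float:
    if log:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def generate_country_table(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a wide country table plus its complete ground truth.

    Returns ``(table, truth)``: ``table`` has missing cells blanked per the
    missingness spec; ``truth`` is the same table before blanking (for
    imputation scoring and parameter-recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_countries):
        r = {"country_code": _synthetic_code(i)}
        g = {k: _draw(rng, *spec.ranges[k]) for k in spec.ranges}
        total = g["total_swi_incidence"]
        dswi = min(g["dswi_incidence"], 0.9 * total)
        r["cabg_per_100k"] = g["cabg_per_100k"]
        r["cabg_per_year"] = max(1.0, round(g["cabg_per_100k"] * g["population"] / 1e5))
        r["sswi_incidence"] = total - dswi
        r["dswi_incidence"] = dswi
        # Deep-SWI care (mediastinitis spectrum) never resolves faster than
        # superficial care.
        g["extra_los_dswi"] = max(g["extra_los_dswi"], g["extra_los_sswi"])
        for k in (
            "readmit_prob_given_swi", "extra_los_sswi", "extra_los_dswi",
            "icu_cost_per_day", "gw_cost_per_day", "baseline_icu_los", "baseline_gw_los",
        ):
            r[k] = g[k]
        rows.append(r)
    truth = pd.DataFrame(rows)

    table = truth.copy()
    for fname in CANONICAL_FIELDS:
        p = spec.missing_prob(fname)
        if p > 0:
            mask = rng.random(spec.n_countries) < p
            table.loc[mask, fname] = np.nan
    return table, truth


def generate_incidence_observations(
    true_factor: float,
    n_patients: int,
    seed: int,
    curve: HillCurveParams = HillCurveParams(),
    reference_day: float = 30.0,
) -> int:
    """Simulate a 30-day surveillance count: SWI cases among ``n_patients``.

    Cases are binomial with success probability
    ``true_factor * hill_cumulative(reference_day) / 100``; used by the
    calibration-recovery tests (observed rate / curve value estimates the
    true scale factor).
    """
    p = true_factor * hill_cumulative(reference_day, curve) / 100.0
    if not 0.0 <= p < 1.0:
        raise ValueError(f"implied incidence fraction {p} outside [0, 1)")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n_patients, p))
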