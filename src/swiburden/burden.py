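"""Monetary burden of SWIs per country and cross-country summaries.

The annual SWI burden of a country is the cost of SWI-attributable excess
resource use at that country's CABG volume:

    total_cost = excess_icu_days * icu_cost_per_day
               + excess_gw_days  * gw_cost_per_day
               + readmit_days    * gw_cost_per_day

(readmission admission days are costed at the general-ward rate; the care
days that follow a readmission are inside the ICU/GW excess terms).  Derived
ratios are the mean cost per SWI (burden / SWI events) and the mean SWI cost
per CABG (burden / procedures).  Cross-country summaries report totals,
per-country shares and median / IQR / min / max with type-7 quartiles;
aggregation runs on unrounded values, rounding is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .country_data import CountryParameters
from .pathway import EventSummary

__all__ = ["BurdenResult", "CrossCountrySummary", "compute_country_burden", "cross_country_summary"]


@dataclass(frozen=True)
class BurdenResult:
    """Per-country burden totals and derived ratios (2017 US$)."""

    country_code: str
    procedures: float
    swi_events: float
    icu_days: float            # SWI-attributable excess ICU days
    gw_days: float             # SWI-attributable excess GW days
    readmit_days: float        # readmission admission days
    readmissions: float
    icu_cost: float
    gw_cost: float
    readmit_cost: float
    r_swi: float | None = None  # inpatient + readmission rate, fraction

    @property
    def total_cost(self) -> float:
        return self.icu_cost + self.gw_cost + self.readmit_cost

    @property
    def cost_per_cabg(self) -> float:
        return self.total_cost / self.procedures

    @property
    def cost_per_swi(self) -> float | None:
        """Mean cost per SWI; ``None`` (not 0) when no events occurred."""
        if self.swi_events <= 0:
            return None
        return self.total_cost / self.swi_events


@dataclass(frozen=True)
class CrossCountrySummary:
    """Aggregates over a set of per-country burden results."""

    total_cost: float
    shares: dict[str, float]
    total_icu_days: float
    total_gw_days: float
    total_readmissions: float
    cost_per_swi_stats: dict[str, float]
    cost_per_cabg_stats: dict[str, float]


def compute_country_burden(events: EventSummary, params: CountryParameters) -> BurdenResult:
    """Cost one country's excess resource use at its daily bed rates."""
    if events.volume <= 0:
        raise ValueError("events must come from a run with positive volume")
    return BurdenResult(
        country_code=params.country_code,
        procedures=events.volume,
        swi_events=events.swi_events,
        icu_days=events.excess_icu_days,
        gw_days=events.excess_gw_days,
        readmit_days=events.readmit_days,
        readmissions=events.readmissions,
        icu_cost=events.excess_icu_days * params.icu_cost_per_day,
        gw_cost=events.excess_gw_days * params.gw_cost_per_day,
        readmit_cost=events.readmit_days * params.gw_cost_per_day,
        r_swi=events.r_swi,
    )


def _stats(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return {
        "median": float(med),
        "iqr_low": float(q1),
        "iqr_high": float(q3),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def cross_country_summary(results: Iterable[BurdenResult]) -> CrossCountrySummary:
    """Totals, shares and order statistics over per-country results."""
    res = list(results)
    if not res:
        raise ValueError("need at least one BurdenResult")
    total = sum(r.total_cost for r in res)
    shares = {r.country_code: (r.total_cost / total if total > 0 else 0.0) for r in res}
    per_swi = [r.cost_per_swi for r in res if r.cost_per_swi is not None]
    return CrossCountrySummary(
        total_cost=total,
        shares=shares,
        total_icu_days=sum(r.icu_days for r in res),
        total_gw_days=sum(r.gw_days for r in res),
        total_readmissions=sum(r.readmissions for r in res),
        cost_per_swi_stats=_stats(per_swi) if per_swi else {},
        cost_per_cabg_stats=_stats([r.cost_per_cabg for r in res]),
    )


def results_to_frame(results: Iterable[BurdenResult]) -> pd.DataFrame:
    """Flatten burden results into a per-country table (unrounded)."""
    rows = []
    for r in results:
        rows.append(
            {
                "country_code": r.country_code,
                "procedures": r.procedures,
                "swi_events": r.swi_events,
                "swi_burden_usd2017": r.total_cost,
                "cost_per_swi_usd2017": r.cost_per_swi,
                "cost_per_cabg_usd2017": r.cost_per_cabg,
                "excess_icu_days": r.icu_days,
                "excess_gw_days": r.gw_days,
                "readmissions": r.readmissions,
            }
        )
    return pd.DataFrame(rows)
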