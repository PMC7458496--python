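"""Value-based purchasing (VBP) calculator for SWI-prevention interventions.

A VBP contract splits the value of preventing SWIs between a hospital and the
seller of a preventive intervention.  The hospital commits a share S_PUR of
its expected SWI savings to purchasing N_INT interventions up front — the
cost of intervention per patient:

    CIPP = (1 - RR) * C_SWI * r_SWI * (S_PUR / 100) / N_INT

and, if an intervention meets its risk-reduction target, pays out a share
S_SAV of the realized net savings per intervention:

    VBP = [ r_SWI * N_PT * C_SWI * (1 - RR) - CIPP * N_INT * N_PT ]
          / (100 * N_INT) * S_SAV

where RR is the relative risk of SWI with the intervention, C_SWI the cost
per SWI, r_SWI the hospital SWI rate (inpatient events plus readmissions,
fraction), and N_PT the annual patient volume.  What remains after purchase
and payouts is the hospital's saving; the three parts sum to the gross
savings exactly.  A published worked example (C_SWI = 12 008, r_SWI = 0.056,
RR = 0.75, S_PUR = S_SAV = 30, N_INT = 3, N_PT = 1200) gives CIPP US$16.81
and VBP US$14 121.84.

Two standard purchasing scenarios are provided for a hospital performing
1000 CABG/yr with interventions targeting a 20% SWI reduction (RR = 0.8):
scenario 1 commits 50% of the burden to two interventions with a 15% savings
share; scenario 2 commits 30% with a 25% savings share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "VBPScenario",
    "VBPResult",
    "SCENARIOS",
    "compute_cipp",
    "compute_vbp",
    "hospital_savings",
    "evaluate_scenario",
    "run_scenario",
]


@dataclass(frozen=True)
class VBPScenario:
    """One VBP contract configuration for one hospital."""

    rr_with_intervention: float   # relative risk of SWI with the intervention
    share_purchase: float         # S_PUR, percent of SWI cost committed to purchase
    n_interventions: int          # N_INT
    share_savings: float          # S_SAV, percent of net savings paid out on success
    n_patients: float             # N_PT, CABG procedures per year
    cost_per_swi: float           # C_SWI, 2017 US$
    swi_rate: float               # r_SWI, inpatient + readmission rate, fraction

    def __post_init__(self) -> None:
        if not 0.0 <= self.rr_with_intervention <= 1.0:
            raise ValueError(f"rr_with_intervention must be in [0, 1], got {self.rr_with_intervention}")
        for name in ("share_purchase", "share_savings"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percent in [0, 100], got {v}")
        if self.n_interventions < 1:
            raise ValueError(f"n_interventions must be >= 1, got {self.n_interventions}")
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.cost_per_swi < 0:
            raise ValueError(f"cost_per_swi must be >= 0, got {self.cost_per_swi}")
        if not 0.0 <= self.swi_rate <= 1.0:
            raise ValueError(f"swi_rate must be a fraction in [0, 1], got {self.swi_rate}")


@dataclass(frozen=True)
class VBPResult:
    """All monetary components of one VBP evaluation (2017 US$)."""

    cipp: float              # per patient
    vbp_payment: float       # per intervention, paid on success
    gross_savings: float     # r * N_PT * C * (1 - RR)
    purchase_cost: float     # cipp * N_INT * N_PT
    hospital_savings: float  # gross - purchase - N_INT * vbp_payment


#: The two published purchasing scenarios (hospital of 1000 CABG/yr,
#: interventions targeting a 20% SWI-rate reduction).
SCENARIOS: dict[int, dict[str, float | int]] = {
    1: {"share_purchase": 50.0, "n_interventions": 2, "share_savings": 15.0,
        "rr_with_intervention": 0.8, "n_patients": 1000},
    2: {"share_purchase": 30.0, "n_interventions": 2, "share_savings": 25.0,
        "rr_with_intervention": 0.8, "n_patients": 1000},
}


def compute_cipp(s: VBPScenario) -> float:
    """Affordable cost of intervention per patient (US$/patient)."""
    return (
        (1.0 - s.rr_with_intervention)
        * s.cost_per_swi
        * s.swi_rate
        * (s.share_purchase / 100.0)
        / s.n_interventions
    )


def compute_vbp(s: VBPScenario, cipp: float | None = None) -> float:
    """Per-intervention success payment (US$/intervention).

    ``cipp`` defaults to :func:`compute_cipp`; passing a rounded CIPP
    reproduces published worked examples to the cent.  A negative payment
    (intervention priced above break-even) is returned with a warning,
    never clamped.
    """
    if cipp is None:
        cipp = compute_cipp(s)
    gross = s.swi_rate * s.n_patients * s.cost_per_swi * (1.0 - s.rr_with_intervention)
    bracket = gross - cipp * s.n_interventions * s.n_patients
    vbp = bracket / (100.0 * s.n_interventions) * s.share_savings
    if vbp < 0:
        warnings.warn(
            f"VBP payment is negative ({vbp:.2f}): CIPP {cipp:.2f} exceeds the "
            "break-even price",
            stacklevel=2,
        )
    return vbp


def hospital_savings(s: VBPScenario, cipp: float, vbp_payment: float) -> float:
    """Hospital's net saving when every intervention meets its target:
    gross savings minus purchase cost minus all success payouts."""
    gross = s.swi_rate * s.n_patients * s.cost_per_swi * (1.0 - s.rr_with_intervention)
    purchase = cipp * s.n_interventions * s.n_patients
    return gross - purchase - s.n_interventions * vbp_payment


def evaluate_scenario(s: VBPScenario) -> VBPResult:
    """CIPP, VBP payment and savings decomposition for one scenario."""
    cipp = compute_cipp(s)
    vbp = compute_vbp(s, cipp)
    gross = s.swi_rate * s.n_patients * s.cost_per_swi * (1.0 - s.rr_with_intervention)
    purchase = cipp * s.n_interventions * s.n_patients
    return VBPResult(
        cipp=cipp,
        vbp_payment=vbp,
        gross_savings=gross,
        purchase_cost=purchase,
        hospital_savings=gross - purchase - s.n_interventions * vbp,
    )


def run_scenario(
    scenario_id: int,
    cost_per_swi_draws: Sequence[float],
    swi_rate_draws: Sequence[float],
    n_patients: float | None = None,
) -> pd.DataFrame:
    """Evaluate a published scenario on per-draw PSA inputs.

    ``cost_per_swi_draws`` and ``swi_rate_draws`` are aligned per-draw values
    (typically from :func:`swiburden.psa.run_psa`).  Returns one row per draw
    with cipp, vbp_payment and hospital_savings; summarize with median and
    range across rows.
    """
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id}; known: {sorted(SCENARIOS)}")
    if len(cost_per_swi_draws) != len(swi_rate_draws):
        raise ValueError("cost and rate draws must be aligned")
    const = dict(SCENARIOS[scenario_id])
    if n_patients is not None:
        const["n_patients"] = n_patients
    rows = []
    for c, r in zip(cost_per_swi_draws, swi_rate_draws):
        s = VBPScenario(cost_per_swi=float(c), swi_rate=float(r), **const)  # type: ignore[arg-type]
        res = evaluate_scenario(s)
        rows.append(
            {"cipp": res.cipp, "vbp_payment": res.vbp_payment,
             "hospital_savings": res.hospital_savings, "gross_savings": res.gross_savings,
             "purchase_cost": res.purchase_cost}
        )
    return pd.DataFrame(rows)
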