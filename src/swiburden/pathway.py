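"""Daily-cycle Markov cohort model of the CABG care pathway.

A patient enters the model at surgery into the ICU (the first ICU day is the
ventilated state ICU_VENT), recovers to the general ward (GW) and is then
discharged home.  On every at-risk day the patient may develop a first
sternal-wound infection, superficial (SSWI) or deep (DSWI), with the daily
hazard taken from the country-calibrated cumulative incidence curve and split
between severities in fixed country-specific proportions.

Infection makes the stated additional length of stay truly additional:
an inpatient who develops an SWI first completes the remainder of the
baseline ICU/GW stay in a parallel infected track (ICU_INF_*/GW_INF_*, no
further first-SWI hazard), then serves the severity-specific SWI-care stay
(SSWI_CARE / DSWI_CARE) before going home.  Onset at home leads, with the
country's readmission probability, to readmission (one admission day in
READMIT, then SWI care); otherwise the case is counted but treated outside
hospital with no modeled bed-day burden.  Patients who complete SWI care
return home and are no longer at risk (HOME_POST_SWI, a bookkeeping
refinement of the home state that keeps the first-SWI hazard calibration
exact).  Deep-SWI care carries a daily death risk calibrated to a
configurable case fatality; DEAD is absorbing.

Dwell times are geometric with mean equal to the stated length of stay
(exit probability 1/mean), so expected baseline stays equal the baseline ICU
and GW LOS inputs and expected SWI-care stays equal the additional-LOS
inputs (up to end-of-horizon truncation and, for deep SWIs, death during
care).  Deep-SWI care days are split between ICU and GW beds by a
configurable fraction.

Two engines share one :class:`TransitionModel`: the deterministic cohort
engine (:func:`run_cohort`, forward propagation of occupancy fractions) and a
patient-level Monte-Carlo oracle (:func:`simulate_patients`) used to verify
the cohort arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .incidence import CalibratedIncidence, hazard_series

if TYPE_CHECKING:
    from .country_data import CountryParameters

__all__ = [
    "STATES",
    "ModelConfig",
    "TransitionModel",
    "CohortTrace",
    "EventSummary",
    "build_transition_model",
    "baseline_transition_model",
    "run_cohort",
    "simulate_patients",
    "extract_events",
]

#: Model states, in matrix order.  The *_INF_S / *_INF_D states are the
#: infected continuation of the baseline stay (superficial / deep pending
#: care); HOME_POST_SWI is the post-infection home state.
STATES: tuple[str, ...] = (
    "ICU_VENT",
    "ICU",
    "GW",
    "HOME",
    "ICU_INF_S",
    "ICU_INF_D",
    "GW_INF_S",
    "GW_INF_D",
    "SSWI_CARE",
    "DSWI_CARE",
    "READMIT",
    "HOME_POST_SWI",
    "DEAD",
)

_IDX = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

#: States whose occupants spend the day in an ICU bed / a GW bed (deep-SWI
#: care is split between the two by ``ModelConfig.deep_icu_share``).
_ICU_STATES = ("ICU_VENT", "ICU", "ICU_INF_S", "ICU_INF_D")
_GW_STATES = ("GW", "GW_INF_S", "GW_INF_D", "SSWI_CARE", "READMIT")
_AT_RISK_INPATIENT = ("ICU_VENT", "ICU", "GW")
_INF_STATES = ("ICU_INF_S", "ICU_INF_D", "GW_INF_S", "GW_INF_D")

_ROW_SUM_TOL = 1e-12
_OCCUPANCY_TOL = 1e-9


@dataclass(frozen=True)
class ModelConfig:
    """Pathway configuration.

    horizon           simulation horizon in daily cycles (90 d captures >85%
                      of the incidence-curve asymptote, K = 23.73 d)
    deep_icu_share    fraction of deep-SWI care days spent in an ICU bed
    dswi_case_fatality  probability a deep-SWI episode ends in death
                      (midpoint of the reported 7–35% in-hospital range)
    """

    horizon: int = 90
    cycle_days: float = 1.0
    deep_icu_share: float = 0.2
    dswi_case_fatality: float = 0.15

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1 cycle, got {self.horizon}")
        if not 0.0 <= self.deep_icu_share <= 1.0:
            raise ValueError(f"deep_icu_share must be in [0, 1], got {self.deep_icu_share}")
        if not 0.0 <= self.dswi_case_fatality < 1.0:
            raise ValueError(f"dswi_case_fatality must be in [0, 1), got {self.dswi_case_fatality}")


@dataclass
class TransitionModel:
    """Per-cycle transition probabilities plus the inputs that produced them.

    ``matrices[t]`` is the row-stochastic matrix applied at the end of day
    ``t+1`` (time-varying because the SWI hazard is).
    """

    matrices: np.ndarray  # (horizon, N_STATES, N_STATES)
    config: ModelConfig
    dswi_share: float
    hazards: np.ndarray   # daily first-SWI hazard, length horizon
    country_code: str = ""

    def __post_init__(self) -> None:
        if self.matrices.shape != (self.config.horizon, N_STATES, N_STATES):
            raise ValueError(f"matrices have wrong shape {self.matrices.shape}")
        if np.any(self.matrices < -_ROW_SUM_TOL) or np.any(self.matrices > 1 + _ROW_SUM_TOL):
            raise ValueError("transition probabilities outside [0, 1]")
        rowsums = self.matrices.sum(axis=2)
        if not np.allclose(rowsums, 1.0, atol=_ROW_SUM_TOL, rtol=0.0):
            worst = np.abs(rowsums - 1.0).max()
            raise ValueError(f"transition rows do not sum to 1 (max deviation {worst:.3e})")


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy and accumulated burden for one cohort run.

    ``occupancy[t]`` holds cohort fractions at the start of day ``t+1``
    (row 0 is the entry distribution); rows sum to 1.  Accumulators are
    scaled by procedure volume.
    """

    occupancy: np.ndarray  # (horizon + 1, N_STATES), fractions
    volume: float
    icu_days: float = 0.0
    gw_days: float = 0.0
    readmit_days: float = 0.0
    sswi_events: float = 0.0
    dswi_events: float = 0.0
    inpatient_swi_events: float = 0.0
    postdischarge_swi_events: float = 0.0
    readmissions: float = 0.0
    deaths: float = 0.0

    @property
    def swi_events(self) -> float:
        return self.sswi_events + self.dswi_events

    def validate(self) -> None:
        rowsums = self.occupancy.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=_OCCUPANCY_TOL, rtol=0.0):
            raise ValueError("cohort occupancy rows do not sum to 1")


@dataclass(frozen=True)
class EventSummary:
    """SWI events and excess resource use relative to a zero-SWI baseline."""

    swi_events: float
    inpatient_rate: float       # fraction of procedures
    readmission_rate: float     # fraction of procedures
    excess_icu_days: float
    excess_gw_days: float
    readmit_days: float
    readmissions: float
    deaths: float
    volume: float

    @property
    def r_swi(self) -> float:
        """Hospital SWI rate: inpatient events plus readmissions, fraction."""
        return self.inpatient_rate + self.readmission_rate


def _exit_prob(mean_days: float) -> float:
    """Geometric-dwell inversion: exit probability giving the stated mean stay.

    Stays shorter than one cycle exit with certainty after the single cycle.
    """
    if mean_days < 0:
        raise ValueError(f"length of stay must be >= 0, got {mean_days}")
    return 1.0 if mean_days <= 1.0 else 1.0 / mean_days


def build_transition_model(
    params: "CountryParameters",
    inc: CalibratedIncidence,
    config: ModelConfig = ModelConfig(),
    hazard_scale: float = 1.0,
) -> TransitionModel:
    """Assemble the per-cycle transition matrices for one country.

    ``hazard_scale`` rescales the daily SWI hazard (0 gives the zero-SWI
    baseline pathway used to measure excess burden).  Raises ``ValueError``
    if any derived probability leaves [0, 1], naming the offending parameter.
    """
    h = hazard_series(inc, config.horizon) * hazard_scale
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("daily SWI hazard outside [0, 1]; check incidence calibration")

    share_d = params.dswi_share
    r = params.readmit_prob_given_swi

    p_icu = _exit_prob(params.baseline_icu_los)
    p_gw = _exit_prob(params.baseline_gw_los)
    p_ss = _exit_prob(params.extra_los_sswi)
    p_ds = _exit_prob(params.extra_los_dswi)
    for name, p in (
        ("baseline_icu_los", p_icu),
        ("baseline_gw_los", p_gw),
        ("extra_los_sswi", p_ss),
        ("extra_los_dswi", p_ds),
    ):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"derived exit probability for {name} outside (0, 1]: {p}")

    # Daily deep-SWI death probability d solving the competing-risks case
    # fatality  CFR = d / (d + (1 - d) * p_exit):  d = k*e / (1 + k*e),
    # k = CFR / (1 - CFR).
    cfr = config.dswi_case_fatality
    k = cfr / (1.0 - cfr)
    d = k * p_ds / (1.0 + k * p_ds)

    P = np.zeros((config.horizon, N_STATES, N_STATES))
    s = _IDX
    for t in range(config.horizon):
        ht = h[t]
        hs, hd = ht * (1.0 - share_d), ht * share_d
        M = P[t]
        # At-risk inpatients: SWI onset diverts to the infected track, which
        # continues the interrupted baseline stay at the same exit rates.
        for st, p_exit, nxt, inf_s, inf_d in (
            ("ICU_VENT", p_icu, "GW", "ICU_INF_S", "ICU_INF_D"),
            ("ICU", p_icu, "GW", "ICU_INF_S", "ICU_INF_D"),
            ("GW", p_gw, "HOME", "GW_INF_S", "GW_INF_D"),
        ):
            M[s[st], s[inf_s]] = hs
            M[s[st], s[inf_d]] = hd
            stay_to = "ICU" if st in ("ICU_VENT", "ICU") else "GW"
            M[s[st], s[nxt]] += (1.0 - ht) * p_exit
            M[s[st], s[stay_to]] += (1.0 - ht) * (1.0 - p_exit)
        # Home, still at risk: onset leads to readmission or to home care.
        M[s["HOME"], s["READMIT"]] = ht * r
        M[s["HOME"], s["HOME_POST_SWI"]] = ht * (1.0 - r)
        M[s["HOME"], s["HOME"]] = 1.0 - ht
        # Infected baseline continuation, then SWI care.
        M[s["ICU_INF_S"], s["GW_INF_S"]] = p_icu
        M[s["ICU_INF_S"], s["ICU_INF_S"]] = 1.0 - p_icu
        M[s["ICU_INF_D"], s["GW_INF_D"]] = p_icu
        M[s["ICU_INF_D"], s["ICU_INF_D"]] = 1.0 - p_icu
        M[s["GW_INF_S"], s["SSWI_CARE"]] = p_gw
        M[s["GW_INF_S"], s["GW_INF_S"]] = 1.0 - p_gw
        M[s["GW_INF_D"], s["DSWI_CARE"]] = p_gw
        M[s["GW_INF_D"], s["GW_INF_D"]] = 1.0 - p_gw
        # SWI care.
        M[s["SSWI_CARE"], s["HOME_POST_SWI"]] = p_ss
        M[s["SSWI_CARE"], s["SSWI_CARE"]] = 1.0 - p_ss
        M[s["DSWI_CARE"], s["DEAD"]] = d
        M[s["DSWI_CARE"], s["HOME_POST_SWI"]] = (1.0 - d) * p_ds
        M[s["DSWI_CARE"], s["DSWI_CARE"]] = (1.0 - d) * (1.0 - p_ds)
        # Readmission: one admission day, then severity-proportional SWI care
        # (the baseline stay is already complete for home-onset cases).
        M[s["READMIT"], s["SSWI_CARE"]] = 1.0 - share_d
        M[s["READMIT"], s["DSWI_CARE"]] = share_d
        # Absorbing / terminal states.
        M[s["HOME_POST_SWI"], s["HOME_POST_SWI"]] = 1.0
        M[s["DEAD"], s["DEAD"]] = 1.0

    return TransitionModel(P, config, share_d, h, country_code=inc.country_code)


def baseline_transition_model(
    params: "CountryParameters",
    inc: CalibratedIncidence,
    config: ModelConfig = ModelConfig(),
) -> TransitionModel:
    """The zero-SWI pathway used as the excess-burden reference."""
    return build_transition_model(params, inc, config, hazard_scale=0.0)


def run_cohort(model: TransitionModel, volume: float = 1.0) -> CohortTrace:
    """Deterministic forward propagation of the cohort.

    The whole cohort enters in ICU_VENT (surgery day).  Occupancy row ``t``
    is lived through day ``t+1``; the final row is terminal and accrues
    nothing.  All accumulators are linear in ``volume``.
    """
    if volume < 0:
        raise ValueError(f"volume must be >= 0, got {volume}")
    H = model.config.horizon
    occ = np.zeros((H + 1, N_STATES))
    occ[0, _IDX["ICU_VENT"]] = 1.0

    trace = CohortTrace(occupancy=occ, volume=volume)
    s = _IDX
    icu_ix = [s[x] for x in _ICU_STATES]
    gw_ix = [s[x] for x in _GW_STATES]
    risk_ix = [s[x] for x in _AT_RISK_INPATIENT]
    inf_s_ix = [s["ICU_INF_S"], s["GW_INF_S"]]
    inf_d_ix = [s["ICU_INF_D"], s["GW_INF_D"]]
    a = model.config.deep_icu_share
    for t in range(H):
        y = occ[t]
        flows = y[:, None] * model.matrices[t]
        occ[t + 1] = flows.sum(axis=0)
        # Day t+1 is spent in the state occupied at the start of the cycle.
        trace.icu_days += y[icu_ix].sum() + a * y[s["DSWI_CARE"]]
        trace.gw_days += y[gw_ix].sum() + (1.0 - a) * y[s["DSWI_CARE"]]
        trace.readmit_days += y[s["READMIT"]]
        inpatient_s = flows[np.ix_(risk_ix, inf_s_ix)].sum()
        inpatient_d = flows[np.ix_(risk_ix, inf_d_ix)].sum()
        home_onset = flows[s["HOME"], s["READMIT"]] + flows[s["HOME"], s["HOME_POST_SWI"]]
        trace.inpatient_swi_events += inpatient_s + inpatient_d
        trace.postdischarge_swi_events += home_onset
        trace.sswi_events += inpatient_s + home_onset * (1.0 - model.dswi_share)
        trace.dswi_events += inpatient_d + home_onset * model.dswi_share
        trace.readmissions += flows[s["HOME"], s["READMIT"]]
        trace.deaths += flows[:, s["DEAD"]].sum() - y[s["DEAD"]]

    trace.validate()
    for fld in (
        "icu_days", "gw_days", "readmit_days", "sswi_events", "dswi_events",
        "inpatient_swi_events", "postdischarge_swi_events", "readmissions", "deaths",
    ):
        setattr(trace, fld, getattr(trace, fld) * volume)
    return trace


def simulate_patients(model: TransitionModel, n: int, seed: int) -> CohortTrace:
    """Patient-level Monte-Carlo oracle sampling the same transition model.

    Returns a :class:`CohortTrace` whose occupancy is the empirical state
    distribution and whose accumulators are sample totals (volume = ``n``).
    Means converge to :func:`run_cohort` values; identical seeds reproduce
    identical output.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    H = model.config.horizon
    s = _IDX
    a = model.config.deep_icu_share
    icu_ix = np.array([s[x] for x in _ICU_STATES])
    gw_ix = np.array([s[x] for x in _GW_STATES])
    risk_ix = np.array([s[x] for x in _AT_RISK_INPATIENT])
    inf_s_ix = np.array([s["ICU_INF_S"], s["GW_INF_S"]])
    inf_d_ix = np.array([s["ICU_INF_D"], s["GW_INF_D"]])

    state = np.full(n, s["ICU_VENT"], dtype=np.int64)
    occ = np.zeros((H + 1, N_STATES))
    occ[0] = np.bincount(state, minlength=N_STATES) / n
    trace = CohortTrace(occupancy=occ, volume=float(n))

    cum = np.cumsum(model.matrices, axis=2)
    for t in range(H):
        in_icu = np.isin(state, icu_ix)
        in_gw = np.isin(state, gw_ix)
        in_ds = state == s["DSWI_CARE"]
        in_re = state == s["READMIT"]
        trace.icu_days += in_icu.sum() + a * in_ds.sum()
        trace.gw_days += in_gw.sum() + (1.0 - a) * in_ds.sum()
        trace.readmit_days += in_re.sum()

        u = rng.random(n)
        nxt = np.empty_like(state)
        for st in np.unique(state):
            mask = state == st
            nxt[mask] = np.searchsorted(cum[t, st], u[mask], side="right")
        np.minimum(nxt, N_STATES - 1, out=nxt)

        at_risk = np.isin(state, risk_ix)
        new_inf_s = np.isin(nxt, inf_s_ix)
        new_inf_d = np.isin(nxt, inf_d_ix)
        inpat_s = (at_risk & new_inf_s).sum()
        inpat_d = (at_risk & new_inf_d).sum()
        home = state == s["HOME"]
        home_readmit = (home & (nxt == s["READMIT"])).sum()
        home_noadmit = (home & (nxt == s["HOME_POST_SWI"])).sum()
        home_onset = home_readmit + home_noadmit
        trace.inpatient_swi_events += inpat_s + inpat_d
        trace.postdischarge_swi_events += home_onset
        trace.sswi_events += inpat_s + home_onset * (1.0 - model.dswi_share)
        trace.dswi_events += inpat_d + home_onset * model.dswi_share
        trace.readmissions += home_readmit
        trace.deaths += ((state != s["DEAD"]) & (nxt == s["DEAD"])).sum()

        state = nxt
        occ[t + 1] = np.bincount(state, minlength=N_STATES) / n

    trace.validate()
    return trace


def extract_events(trace: CohortTrace, baseline: CohortTrace) -> EventSummary:
    """Summarize SWI events and excess care days against a zero-SWI baseline.

    Both traces must come from the same volume and horizon.  The hospital SWI
    rate ``r_swi`` is the inpatient event rate plus the readmission rate.
    Excess GW days exclude the readmission admission days, which are reported
    (and costed) as their own component.
    """
    if trace.occupancy.shape != baseline.occupancy.shape:
        raise ValueError("trace and baseline have mismatched horizons")
    if abs(trace.volume - baseline.volume) > 1e-9:
        raise ValueError("trace and baseline have mismatched volumes")
    vol = trace.volume
    return EventSummary(
        swi_events=trace.swi_events,
        inpatient_rate=trace.inpatient_swi_events / vol if vol > 0 else 0.0,
        readmission_rate=trace.readmissions / vol if vol > 0 else 0.0,
        excess_icu_days=trace.icu_days - baseline.icu_days,
        excess_gw_days=trace.gw_days - baseline.gw_days - trace.readmit_days,
        readmit_days=trace.readmit_days,
        readmissions=trace.readmissions,
        deaths=trace.deaths,
        volume=vol,
    )
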