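"""Probabilistic sensitivity analysis over the country burden pipeline.

Each iteration draws a full parameter set around the country's point
estimates, reruns calibration → pathway → burden end-to-end, and the draws
are summarized as median / range / IQR / SD per metric.  Distribution
families follow common health-economic practice:

* costs, lengths of stay and procedure volume — gamma, matched to the point
  estimate by mean with SD either derived from a stored cross-country IQR
  (imputed cells) or defaulting to 20% of the mean;
* incidences and probabilities — beta, matched by mean, with the same SD rule
  truncated to keep the beta parameterization feasible.

Reproducibility: each (country, draw, field) triple gets its own independent
numpy substream seeded from ``(seed, country, draw, field)``, so adding or
removing one field never perturbs the draws of another, and a fixed seed
gives bit-identical results.  The default of 52 iterations matches the
study design this model reproduces; it is a config default, not a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import BurdenResult, compute_country_burden
from .country_data import CANONICAL_FIELDS, CountryParameters
from .incidence import HillCurveParams, calibrate
from .pathway import ModelConfig, baseline_transition_model, build_transition_model, extract_events, run_cohort

__all__ = ["PSAConfig", "PSASummary", "sample_parameters", "run_psa", "summarize", "draws_to_frame"]

#: Fields drawn from a gamma distribution (non-negative continuous scale).
GAMMA_FIELDS = (
    "cabg_per_year",
    "extra_los_sswi",
    "extra_los_dswi",
    "icu_cost_per_day",
    "gw_cost_per_day",
    "baseline_icu_los",
    "baseline_gw_los",
)
#: Fields drawn from a beta distribution (bounded rates; incidences are
#: sampled on the fraction scale and converted back to percent).
BETA_FIELDS = ("sswi_incidence", "dswi_incidence", "readmit_prob_given_swi")

#: IQR width of a normal in SD units; used to turn a stored IQR into an SD.
_IQR_TO_SD = 1.3489795003921634


@dataclass(frozen=True)
class PSAConfig:
    """PSA settings: iteration count, seed and per-field spread overrides.

    ``spreads`` maps field name -> SD (same units as the field); fields
    without an entry use ``default_sd_frac`` of the point estimate, unless an
    imputation IQR is supplied at sampling time.  A spread of 0 pins the
    field to its point estimate.
    """

    iterations: int = 52
    seed: int = 0
    default_sd_frac: float = 0.2
    spreads: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.iterations < 2:
            raise ValueError(f"iterations must be >= 2, got {self.iterations}")
        if self.default_sd_frac < 0:
            raise ValueError("default_sd_frac must be >= 0")
        for k, v in self.spreads.items():
            if k not in CANONICAL_FIELDS:
                raise ValueError(f"spread for unknown field {k!r}")
            if v < 0:
                raise ValueError(f"spread for {k!r} must be >= 0, got {v}")


@dataclass(frozen=True)
class PSASummary:
    """Order statistics and SD per metric over the PSA draws."""

    n_draws: int
    metrics: dict[str, dict[str, float]]  # metric -> {median,min,max,iqr_low,iqr_high,sd}


def _field_rng(seed: int, country_code: str, draw_index: int, field_index: int) -> np.random.Generator:
    country_key = int.from_bytes(country_code.encode("utf-8"), "big")
    return np.random.default_rng(np.random.SeedSequence([seed, country_key, draw_index, field_index]))


def _field_sd(
    fname: str,
    point: float,
    cfg: PSAConfig,
    uncertainty: Mapping[str, tuple[float, float]] | None,
    provenance: Mapping[str, str],
) -> float:
    if fname in cfg.spreads:
        return float(cfg.spreads[fname])
    if (
        uncertainty is not None
        and provenance.get(fname) == "imputed"
        and fname in uncertainty
    ):
        q1, q3 = uncertainty[fname]
        sd = (q3 - q1) / _IQR_TO_SD
        if sd > 0:
            return sd
    return cfg.default_sd_frac * abs(point)


def sample_parameters(
    params: CountryParameters,
    cfg: PSAConfig,
    draw_index: int,
    uncertainty: Mapping[str, tuple[float, float]] | None = None,
) -> CountryParameters:
    """Draw one parameter set around ``params`` for PSA iteration ``draw_index``.

    ``uncertainty`` optionally maps imputed field names to the cross-country
    IQR stored at imputation time; that IQR is treated as the central 50%
    interval of the sampling distribution (SD = width / 1.349).  All draws
    respect the type invariants of :class:`CountryParameters`.
    """
    drawn: dict[str, float] = {}
    for fi, fname in enumerate(CANONICAL_FIELDS):
        point = float(getattr(params, fname))
        sd = _field_sd(fname, point, cfg, uncertainty, params.provenance)
        if sd == 0 or point == 0:
            drawn[fname] = point
            continue
        rng = _field_rng(cfg.seed, params.country_code, draw_index, fi)
        if fname in GAMMA_FIELDS:
            shape = (point / sd) ** 2
            scale = sd**2 / point
            drawn[fname] = float(rng.gamma(shape, scale))
        else:
            # Beta on the fraction scale; percent fields are /100 first.
            unit = 100.0 if fname.endswith("_incidence") else 1.0
            mu = point / unit
            s = sd / unit
            if mu >= 1.0:
                raise ValueError(f"beta mean for {fname!r} must be < 1, got {mu}")
            s_max = np.sqrt(mu * (1.0 - mu))
            s = min(s, 0.95 * s_max)  # keep the parameterization feasible
            nu = mu * (1.0 - mu) / s**2 - 1.0
            drawn[fname] = float(rng.beta(mu * nu, (1.0 - mu) * nu)) * unit

    # Keep the severity split valid if both incidences drew high.
    total = drawn["sswi_incidence"] + drawn["dswi_incidence"]
    if total > 100.0:
        drawn["sswi_incidence"] *= 100.0 / total
        drawn["dswi_incidence"] *= 100.0 / total
    drawn["cabg_per_year"] = max(drawn["cabg_per_year"], 1.0)
    return replace(params, **drawn)


def run_psa(
    params: CountryParameters,
    cfg: PSAConfig,
    model_config: ModelConfig = ModelConfig(),
    curve: HillCurveParams = HillCurveParams(),
    uncertainty: Mapping[str, tuple[float, float]] | None = None,
    reference_day: float = 30.0,
) -> list[BurdenResult]:
    """Run the full calibrate → pathway → burden pipeline once per draw."""
    results: list[BurdenResult] = []
    for i in range(cfg.iterations):
        p = sample_parameters(params, cfg, i, uncertainty)
        inc = calibrate(p.total_swi_incidence, curve, reference_day, p.country_code)
        model = build_transition_model(p, inc, model_config)
        base = baseline_transition_model(p, inc, model_config)
        trace = run_cohort(model, p.cabg_per_year)
        base_trace = run_cohort(base, p.cabg_per_year)
        results.append(compute_country_burden(extract_events(trace, base_trace), p))
    return results


def draws_to_frame(draws: Sequence[BurdenResult]) -> pd.DataFrame:
    """One row per draw with the metrics the summary statistics run over."""
    return pd.DataFrame(
        {
            "total_cost": [d.total_cost for d in draws],
            "cost_per_swi": [d.cost_per_swi for d in draws],
            "cost_per_cabg": [d.cost_per_cabg for d in draws],
            "icu_days": [d.icu_days for d in draws],
            "gw_days": [d.gw_days for d in draws],
            "readmissions": [d.readmissions for d in draws],
            "swi_events": [d.swi_events for d in draws],
            "r_swi": [d.r_swi for d in draws],
        }
    )


def summarize(draws: Sequence[BurdenResult] | pd.DataFrame) -> PSASummary:
    """Median, range, type-7 IQR and sample SD (ddof=1) per metric."""
    frame = draws if isinstance(draws, pd.DataFrame) else draws_to_frame(draws)
    if len(frame) < 2:
        raise ValueError("need at least 2 draws to summarize")
    metrics: dict[str, dict[str, float]] = {}
    for col in frame.columns:
        arr = frame[col].to_numpy(dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            continue
        q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
        metrics[col] = {
            "median": float(med),
            "min": float(arr.min()),
            "max": float(arr.max()),
            "iqr_low": float(q1),
            "iqr_high": float(q3),
            "sd": float(np.std(arr, ddof=1)),
        }
    return PSASummary(n_draws=len(frame), metrics=metrics)
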