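"""End-to-end runner: country table in, burden / PSA / VBP tables out.

:func:`run_full_analysis` wires the whole pipeline — validate and impute the
country table, calibrate each country's incidence curve, run the Markov
pathway against its zero-SWI baseline, cost the excess, run the PSA, and
evaluate the two published VBP scenarios — and writes:

* ``table1.csv`` — deterministic base-case burden per country,
* ``table2.csv`` — PSA median (range) of cost / ICU days / GW days /
  readmissions per country,
* ``table3.csv`` — VBP scenario medians (ranges) per country,
* ``boxplot.csv`` — per-country cost-per-CABG draw statistics,
* ``summary.json`` — cross-country totals and medians.

Every file starts with ``#``-prefixed provenance lines (package version,
seed, config hash); given a fixed seed the outputs are byte-identical
across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .burden import BurdenResult, compute_country_burden, cross_country_summary, results_to_frame
from .country_data import (
    CountryParameters,
    filter_included_countries,
    impute_missing,
    read_country_table,
    table_to_parameters,
    write_country_table,
)
from .incidence import HillCurveParams, calibrate
from .pathway import (
    EventSummary,
    ModelConfig,
    baseline_transition_model,
    build_transition_model,
    extract_events,
    run_cohort,
)
from .psa import PSAConfig, run_psa, draws_to_frame
from .vbp import SCENARIOS, run_scenario

__all__ = ["RunConfig", "run_country_base_case", "run_full_analysis", "emit_boxplot_data"]

log = logging.getLogger("swiburden")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run."""

    countries_csv: str
    out_dir: str
    seed: int = 0
    horizon: int = 90
    reference_day: float = 30.0
    psa_iterations: int = 52
    scenario_ids: Sequence[int] = (1, 2)
    scenario_n_patients: float = 1000.0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (not file locations)."""
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("countries_csv", "out_dir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_country_base_case(
    params: CountryParameters,
    model_config: ModelConfig = ModelConfig(),
    curve: HillCurveParams = HillCurveParams(),
    reference_day: float = 30.0,
) -> tuple[BurdenResult, EventSummary]:
    """Deterministic calibrate → pathway → burden run for one country."""
    inc = calibrate(params.total_swi_incidence, curve, reference_day, params.country_code)
    model = build_transition_model(params, inc, model_config)
    base = baseline_transition_model(params, inc, model_config)
    trace = run_cohort(model, params.cabg_per_year)
    base_trace = run_cohort(base, params.cabg_per_year)
    events = extract_events(trace, base_trace)
    return compute_country_burden(events, params), events


def emit_boxplot_data(draw_frames: dict[str, pd.DataFrame], metric: str = "cost_per_cabg") -> pd.DataFrame:
    """Per-country distribution records for box plots: median, mean, IQR, SD.

    ``draw_frames`` maps country code to its per-draw metric frame (from
    :func:`swiburden.psa.draws_to_frame`).
    """
    rows = []
    for cc, frame in draw_frames.items():
        arr = frame[metric].to_numpy(dtype=float)
        if arr.size < 2:
            raise ValueError(f"need >= 2 draws for {cc}, got {arr.size}")
        q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
        rows.append(
            {
                "country_code": cc,
                "metric": metric,
                "median": float(med),
                "mean": float(arr.mean()),
                "iqr_low": float(q1),
                "iqr_high": float(q3),
                "sd": float(np.std(arr, ddof=1)),
                "n_draws": int(arr.size),
            }
        )
    return pd.DataFrame(rows)


def _fmt_range(med: float, lo: float, hi: float) -> str:
    return f"{med:.2f} ({lo:.2f} to {hi:.2f})"


def run_full_analysis(cfg: RunConfig) -> dict[str, object]:
    """Run the whole pipeline and write the report bundle to ``cfg.out_dir``.

    Returns the bundle in memory: per-country burden results, PSA draw
    frames, scenario tables and the cross-country summary.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"swiburden {__version__}",
        f"seed {cfg.seed}",
        f"config {cfg.config_hash()}",
    ]

    t0 = time.perf_counter()
    table = read_country_table(cfg.countries_csv)
    included, report = filter_included_countries(table)
    if not len(included):
        raise ValueError("no country passes the inclusion filter (>= 5 of 10 parameters)")
    completed, iqr = impute_missing(included)
    params_list = table_to_parameters(completed)
    log.info("loaded %d countries (%d excluded) in %.2fs",
             len(params_list), int((~report["included"]).sum()), time.perf_counter() - t0)

    model_cfg = ModelConfig(horizon=cfg.horizon)
    curve = HillCurveParams()

    # --- deterministic base case (table 1) ---
    t0 = time.perf_counter()
    base_results: list[BurdenResult] = []
    events_by_cc: dict[str, EventSummary] = {}
    for p in params_list:
        res, ev = run_country_base_case(p, model_cfg, curve, cfg.reference_day)
        base_results.append(res)
        events_by_cc[p.country_code] = ev
    table1 = results_to_frame(base_results).round(2)
    write_country_table(table1, out / "table1.csv", header)
    log.info("base case for %d countries in %.2fs", len(params_list), time.perf_counter() - t0)

    # --- PSA (table 2) ---
    t0 = time.perf_counter()
    psa_cfg = PSAConfig(iterations=cfg.psa_iterations, seed=cfg.seed)
    draw_frames: dict[str, pd.DataFrame] = {}
    rows2 = []
    for p in params_list:
        draws = run_psa(p, psa_cfg, model_cfg, curve, uncertainty=iqr, reference_day=cfg.reference_day)
        frame = draws_to_frame(draws)
        draw_frames[p.country_code] = frame
        rows2.append(
            {
                "country_code": p.country_code,
                "cost_burden_musd2017": _fmt_range(
                    *(np.percentile(frame["total_cost"], 50) / 1e6,
                      frame["total_cost"].min() / 1e6, frame["total_cost"].max() / 1e6)
                ),
                "icu_days": _fmt_range(np.percentile(frame["icu_days"], 50),
                                       frame["icu_days"].min(), frame["icu_days"].max()),
                "gw_days": _fmt_range(np.percentile(frame["gw_days"], 50),
                                      frame["gw_days"].min(), frame["gw_days"].max()),
                "readmissions": _fmt_range(np.percentile(frame["readmissions"], 50),
                                           frame["readmissions"].min(), frame["readmissions"].max()),
            }
        )
        frame.assign(country_code=p.country_code).round(6).to_csv(
            out / f"draws_{p.country_code}.csv", index=False
        )
    table2 = pd.DataFrame(rows2)
    write_country_table(table2, out / "table2.csv", header)
    log.info("PSA (%d iterations/country) in %.2fs", cfg.psa_iterations, time.perf_counter() - t0)

    # --- VBP scenarios (table 3) ---
    t0 = time.perf_counter()
    rows3 = []
    for p in params_list:
        frame = draw_frames[p.country_code]
        row: dict[str, object] = {"country_code": p.country_code}
        for sid in cfg.scenario_ids:
            sc = run_scenario(sid, frame["cost_per_swi"].tolist(), frame["r_swi"].tolist(),
                              n_patients=cfg.scenario_n_patients)
            for col in ("cipp", "vbp_payment", "hospital_savings"):
                arr = sc[col].to_numpy()
                row[f"scenario{sid}_{col}"] = _fmt_range(
                    float(np.percentile(arr, 50)), float(arr.min()), float(arr.max())
                )
        rows3.append(row)
    table3 = pd.DataFrame(rows3)
    write_country_table(table3, out / "table3.csv", header)
    log.info("VBP scenarios %s in %.2fs", tuple(cfg.scenario_ids), time.perf_counter() - t0)

    # --- box-plot data + summary ---
    box = emit_boxplot_data(draw_frames).round(4)
    write_country_table(box, out / "boxplot.csv", header)

    summary = cross_country_summary(base_results)
    summary_payload = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_countries": len(params_list),
        "total_cost_usd2017": summary.total_cost,
        "shares": summary.shares,
        "total_excess_icu_days": summary.total_icu_days,
        "total_excess_gw_days": summary.total_gw_days,
        "total_readmissions": summary.total_readmissions,
        "cost_per_swi": summary.cost_per_swi_stats,
        "cost_per_cabg": summary.cost_per_cabg_stats,
    }
    (out / "summary.json").write_text(json.dumps(summary_payload, indent=2, sort_keys=True))

    return {
        "base_results": base_results,
        "events": events_by_cc,
        "draws": draw_frames,
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "boxplot": box,
        "summary": summary,
        "exclusion_report": report,
        "imputation_iqr": iqr,
    }
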