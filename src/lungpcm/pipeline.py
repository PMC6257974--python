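"""End-to-end orchestration: data -> trends -> cascade -> PSA -> reports.

The pipeline either reads incidence/population CSVs named in the run config
or generates the bundled synthetic scenario (published last-segment APCs as
generating trends over each country's registry coverage years, synthetic
baseline demographics).  When calibration is on, each country's baseline
incidence level is rescaled so that its 2016 deterministic second-LOT count
matches the published projection anchor; by linearity of the cascade in the
incidence level this is exact and leaves growth rates untouched.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import synthetic
from .cascade import (CountryEngine, PatientCountTable, build_engines, default_params,
                      run_deterministic)
from .config import RunConfig
from .datasets import load_published_projections
from .exceptions import ConfigurationError
from .psa import ProbabilisticCounts, PSAConfig, run_psa
from .trends import IncidenceSeries, JoinpointFit, fit_summary_frame, select_joinpoints

log = logging.getLogger("lungpcm")


def build_inputs(config: RunConfig) -> tuple[list[IncidenceSeries], pd.DataFrame]:
    """Incidence series and population projection for the run."""
    if config.incidence_csv:
        series = synthetic.read_incidence_csv(config.incidence_csv)
        series = [s for s in series if s.country in config.countries]
    else:
        specs = synthetic.baseline_trend_specs(config.countries, noise_cv=config.noise_cv)
        series = [synthetic.generate_registry_series(s, seed=_stratum_seed(config.seed, i))
                  for i, s in enumerate(specs)]
    if config.population_csv:
        population = pd.read_csv(config.population_csv, comment="#")
    else:
        population = synthetic.baseline_population(config.countries)
    return series, population


def _stratum_seed(master: int, index: int) -> int:
    return (master * 100003 + 7919 * index + 1) % (2 ** 31)


def fit_all_trends(series: Sequence[IncidenceSeries], config: RunConfig
                   ) -> dict[str, list[JoinpointFit]]:
    """Joinpoint fit per stratum, grouped by country."""
    fits: dict[str, list[JoinpointFit]] = {}
    for i, s in enumerate(series):
        fit = select_joinpoints(
            s, max_joinpoints=config.trend.max_joinpoints, alpha=config.trend.alpha,
            n_perm=config.trend.n_perm, seed=_stratum_seed(config.seed, 10 ** 6 + i))
        fits.setdefault(s.country, []).append(fit)
    return fits


def calibration_scales(
    engines: Mapping[str, CountryEngine],
    params_by_country: Mapping[str, "CountryParams"],
    anchor_year: int = 2016,
    anchor_lot: str = "second",
) -> dict[str, float]:
    """Per-country incidence scale factors matching the published anchor.

    The cascade is linear in the incidence level, so a single unscaled run
    gives the exact factor: ``scale = anchor / unscaled_count``.
    """
    anchors = load_published_projections()
    anchors = anchors[(anchors["year"] == anchor_year) & (anchors["lot"] == anchor_lot)]
    anchors = anchors.set_index("country")["deterministic"]
    fits = {c: e.fits for c, e in engines.items()}
    for c, e in engines.items():
        if anchor_year not in e.out_years:
            raise ConfigurationError(
                f"calibration anchor year {anchor_year} outside forecast years "
                f"{e.out_years[0]}-{e.out_years[-1]} for {c}")
    base = run_deterministic(fits, None, params_by_country, engines=engines)
    scales = {}
    for country in engines:
        if country not in anchors.index:
            raise ConfigurationError(f"no published anchor for country {country}")
        unscaled = base.lookup(country, anchor_year, anchor_lot, rounded=False)
        scales[country] = float(anchors.loc[country]) / unscaled
    return scales


@dataclass
class ForecastResult:
    config: RunConfig
    fits: dict[str, list[JoinpointFit]]
    scales: dict[str, float]
    deterministic: PatientCountTable
    probabilistic: ProbabilisticCounts | None
    timings: dict[str, float]


def run_forecast(config: RunConfig, with_psa: bool = True) -> ForecastResult:
    """Run the full pipeline in memory (no file output)."""
    timings = {}
    t0 = time.perf_counter()
    series, population = build_inputs(config)
    timings["inputs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fits = fit_all_trends(series, config)
    timings["trends"] = time.perf_counter() - t0

    params = {c: config.country_params.get(c) or default_params(c) for c in config.countries}
    engines = build_engines(fits, population, config.years)
    scales = (calibration_scales(engines, params) if config.calibrate
              else {c: 1.0 for c in config.countries})

    t0 = time.perf_counter()
    det = run_deterministic(fits, population, params, years=config.years,
                            survival_lag=config.survival_lag, rate_scale=scales,
                            engines=engines)
    timings["deterministic"] = time.perf_counter() - t0

    prob = None
    if with_psa:
        t0 = time.perf_counter()
        psa_cfg = PSAConfig(n_sims=config.psa.n_sims, seed=config.seed,
                            rel_halfwidth=config.psa.rel_halfwidth,
                            stage_ess=config.psa.stage_ess, vary_apc=config.psa.vary_apc)
        prob = run_psa(fits, population, params, psa_cfg, years=config.years,
                       survival_lag=config.survival_lag, rate_scale=scales,
                       engines=engines)
        timings["psa"] = time.perf_counter() - t0

    for stage, dt in timings.items():
        log.info("stage %-14s %6.2f s", stage, dt)
    return ForecastResult(config=config, fits=fits, scales=scales,
                          deterministic=det, probabilistic=prob, timings=timings)


# ---------------------------------------------------------------------------
# File output

def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# lungpcm config_hash={config.config_hash()} seed={config.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def write_outputs(result: ForecastResult) -> dict[str, Path]:
    """Write trend-fit, deterministic and PSA CSVs to the configured out_dir."""
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths = {}

    all_fits = [f for fits in result.fits.values() for f in fits]
    paths["trend_fits"] = out / "trend_fits.csv"
    _write_csv(fit_summary_frame(all_fits), paths["trend_fits"], cfg)

    paths["counts_cells"] = out / "patient_counts_by_histology.csv"
    _write_csv(result.deterministic.cells, paths["counts_cells"], cfg)

    paths["counts_totals"] = out / "patient_counts_totals.csv"
    _write_csv(result.deterministic.totals(), paths["counts_totals"], cfg)

    if result.probabilistic is not None:
        psa_df = result.probabilistic.table.copy()
        psa_df["n_sims"] = result.probabilistic.n_sims
        psa_df["seed"] = result.probabilistic.seed
        paths["psa"] = out / "psa_counts.csv"
        _write_csv(psa_df, paths["psa"], cfg)
    return paths


def summary_table(result: ForecastResult, years: Sequence[int] | None = None) -> pd.DataFrame:
    """Report-style summary: deterministic count plus PSA mean and 95% CI per
    country/year/LOT, both unrounded and rounded to the nearest 100."""
    det = result.deterministic.totals()
    if years is not None:
        det = det[det["year"].isin(list(years))]
    if result.probabilistic is not None:
        det = det.merge(result.probabilistic.table, on=["country", "year", "lot"], how="left")
        for col in ("mean", "ci_low", "ci_high"):
            det[f"{col}_rounded"] = PatientCountTable.round100(det[col])
    return det.reset_index(drop=True)
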