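"""The deterministic patient count model (PCM) cascade.

Annual incident lung cancer counts are converted into counts of advanced
NSCLC patients receiving second and third line of therapy (LOT), per country,
year and histology:

1. morphology: exclude SCLC, keep the NSCLC share;
2. stage at diagnosis: redistribute the "unknown" mass pro rata, split stage
   III into IIIA/IIIB, classify early (I, II, IIIA) vs advanced (IIIB, IV);
3. progression: early-stage cohorts from the prior ten diagnosis years enter
   the advanced pool according to per-stage Weibull annual interval
   probabilities (cure beyond ten years);
4. treatment: remove the best-supportive-care share, split the systemic-
   eligible advanced pool by histology, and apply per-histology LOT rates.

Counts are attributed to the calendar year of advanced-disease entry; an
optional survival-lag mode defers part of each year's LOT counts to the next
year, weighted by post-progression survival.  Reported tables are rounded to
the nearest 100 patients; all internal arithmetic is unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, ValidationError
from .progression import MortalityModel, ProgressionModel
from .trends import JoinpointFit

EARLY_STAGES = ("I", "II", "IIIA")
STAGES = ("I", "II", "III", "IV")
HISTOLOGIES = ("squamous", "nonsquamous")
LOTS = ("first", "second", "third")

STAGE_SUM_TOL = 0.2  # percentage points of slack on the published stage rows


@dataclass(frozen=True)
class CountryParams:
    """Country-level parameter bundle (all values in percent unless noted).

    ``stage_dist`` carries the published I/II/III/IV/unknown percentages;
    ``pct_IIIb_of_III`` splits stage III into IIIA (early) and IIIB
    (advanced).  ``lot_rates[histology][lot]`` is the share of the systemic-
    eligible advanced pool receiving that line of therapy.
    """

    country: str
    pct_nsclc: float
    pct_squamous: float
    pct_nonsquamous: float
    stage_dist: Mapping[str, float]
    pct_IIIb_of_III: float
    recurrence_5yr: Mapping[str, float]
    median_os_months: Mapping[str, float]
    pct_bsc: float
    pct_eligible: float
    lot_rates: Mapping[str, Mapping[str, float]]

    def __post_init__(self):
        object.__setattr__(self, "stage_dist", dict(self.stage_dist))
        object.__setattr__(self, "recurrence_5yr", dict(self.recurrence_5yr))
        object.__setattr__(self, "median_os_months", dict(self.median_os_months))
        object.__setattr__(self, "lot_rates",
                           {h: dict(v) for h, v in self.lot_rates.items()})
        errs = self.validation_errors()
        if errs:
            raise ValidationError(f"{self.country}: " + "; ".join(errs))

    def validation_errors(self) -> list[str]:
        """All invariant violations (empty when valid)."""
        errs = []
        pct_fields = {
            "pct_nsclc": self.pct_nsclc, "pct_squamous": self.pct_squamous,
            "pct_nonsquamous": self.pct_nonsquamous,
            "pct_IIIb_of_III": self.pct_IIIb_of_III,
            "pct_bsc": self.pct_bsc, "pct_eligible": self.pct_eligible,
        }
        for stage in list(STAGES) + ["unknown"]:
            if stage not in self.stage_dist:
                errs.append(f"stage_dist missing entry {stage!r}")
            else:
                pct_fields[f"stage_dist[{stage}]"] = self.stage_dist[stage]
        for s in EARLY_STAGES:
            if s not in self.recurrence_5yr:
                errs.append(f"recurrence_5yr missing stage {s!r}")
            else:
                pct_fields[f"recurrence_5yr[{s}]"] = self.recurrence_5yr[s]
        for h in HISTOLOGIES:
            for lot in LOTS:
                try:
                    pct_fields[f"lot_rates[{h}][{lot}]"] = self.lot_rates[h][lot]
                except KeyError:
                    errs.append(f"lot_rates missing {h}/{lot}")
        for name, v in pct_fields.items():
            if not (0.0 <= v <= 100.0):
                errs.append(f"{name} must be in [0, 100], got {v}")
        ssum = sum(self.stage_dist.get(s, 0.0) for s in list(STAGES) + ["unknown"])
        if abs(ssum - 100.0) > STAGE_SUM_TOL:
            errs.append(f"stage percentages sum to {ssum:.3f}, expected 100 +/- {STAGE_SUM_TOL}")
        if abs(self.pct_bsc + self.pct_eligible - 100.0) > 1e-6:
            errs.append(
                f"pct_bsc ({self.pct_bsc}) + pct_eligible ({self.pct_eligible}) must equal 100")
        if abs(self.pct_squamous + self.pct_nonsquamous - 100.0) > STAGE_SUM_TOL:
            errs.append("histology shares must sum to 100")
        for h in HISTOLOGIES:
            r = self.lot_rates.get(h, {})
            if all(k in r for k in LOTS) and not (r["third"] <= r["second"] <= r["first"]):
                errs.append(f"{h} LOT rates must satisfy third <= second <= first, got {r}")
        for h in HISTOLOGIES:
            if self.median_os_months.get(h, 1.0) <= 0:
                errs.append(f"median OS for {h} must be > 0")
        return errs

    @classmethod
    def from_dict(cls, country: str, d: Mapping) -> "CountryParams":
        return cls(
            country=country,
            pct_nsclc=float(d["pct_nsclc"]),
            pct_squamous=float(d["pct_squamous"]),
            pct_nonsquamous=float(d["pct_nonsquamous"]),
            stage_dist={k: float(v) for k, v in d["stage_dist"].items()},
            pct_IIIb_of_III=float(d["pct_IIIb_of_III"]),
            recurrence_5yr={k: float(v) for k, v in d["recurrence_5yr"].items()},
            median_os_months={k: float(v) for k, v in d["median_os_months"].items()},
            pct_bsc=float(d["pct_bsc"]),
            pct_eligible=float(d["pct_eligible"]),
            lot_rates={h: {k: float(v) for k, v in r.items()}
                       for h, r in d["lot_rates"].items()},
        )

    def to_dict(self) -> dict:
        return {
            "pct_nsclc": self.pct_nsclc, "pct_squamous": self.pct_squamous,
            "pct_nonsquamous": self.pct_nonsquamous,
            "stage_dist": dict(self.stage_dist),
            "pct_IIIb_of_III": self.pct_IIIb_of_III,
            "recurrence_5yr": dict(self.recurrence_5yr),
            "median_os_months": dict(self.median_os_months),
            "pct_bsc": self.pct_bsc, "pct_eligible": self.pct_eligible,
            "lot_rates": {h: dict(r) for h, r in self.lot_rates.items()},
        }

    def histology_share(self, histology: str) -> float:
        return {"squamous": self.pct_squamous, "nonsquamous": self.pct_nonsquamous}[histology]

    def progression_models(self, shapes: Mapping[str, float] | None = None
                           ) -> dict[str, ProgressionModel]:
        """Per-stage Weibull progression models calibrated on the published
        five-year recurrence proportions (shape defaults to 1)."""
        shapes = shapes or {}
        return {
            s: ProgressionModel.from_five_year_recurrence(
                s, self.recurrence_5yr[s] / 100.0, beta=float(shapes.get(s, 1.0)))
            for s in EARLY_STAGES
        }

    def mortality_models(self) -> dict[str, MortalityModel]:
        return {h: MortalityModel(histology=h, median_os_months=self.median_os_months[h])
                for h in HISTOLOGIES}


def default_params(country: str) -> CountryParams:
    """Bundled published parameters for one of the four modeled countries."""
    from .datasets import load_country_params_dict
    return CountryParams.from_dict(country, load_country_params_dict(country))


# ---------------------------------------------------------------------------
# Cascade steps

def redistribute_unknown_stage(stage_dist: Mapping[str, float],
                               mode: str = "redistribute") -> dict[str, float]:
    """Allocate the 'unknown' stage mass pro rata across stages I-IV.

    The default returns a four-stage distribution summing to exactly 100.
    ``mode='drop'`` instead discards the unknown mass (the result then sums
    to 100 minus the unknown share), which silently shrinks incidence and is
    provided only for sensitivity checks.
    """
    known = {s: stage_dist[s] for s in STAGES}
    total_known = sum(known.values())
    if total_known <= 0:
        raise DomainError("degenerate stage distribution: all mass is 'unknown'")
    if mode == "drop":
        return known
    if mode != "redistribute":
        raise ValidationError(f"mode must be 'redistribute' or 'drop', got {mode!r}")
    return {s: v * 100.0 / total_known for s, v in known.items()}


@dataclass(frozen=True)
class CohortSlices:
    """One diagnosis year's cohort, sliced by the cascade's first stages."""

    total: float
    nsclc: float
    sclc_excluded: float
    early: dict[str, float]          # counts at stages I, II, IIIA
    advanced_at_dx: float            # IIIB + IV

    @property
    def early_total(self) -> float:
        return sum(self.early.values())


def split_cohort(cases: float, params: CountryParams) -> CohortSlices:
    """Split one year's incident lung cancer count into the cascade slices."""
    if cases < 0:
        raise DomainError(f"cases must be >= 0, got {cases}")
    nsclc = cases * params.pct_nsclc / 100.0
    dist = redistribute_unknown_stage(params.stage_dist)
    p_IIIb = params.pct_IIIb_of_III / 100.0
    early = {
        "I": nsclc * dist["I"] / 100.0,
        "II": nsclc * dist["II"] / 100.0,
        "IIIA": nsclc * dist["III"] / 100.0 * (1.0 - p_IIIb),
    }
    advanced = nsclc * (dist["IV"] / 100.0 + dist["III"] / 100.0 * p_IIIb)
    return CohortSlices(
        total=float(cases), nsclc=nsclc, sclc_excluded=float(cases) - nsclc,
        early=early, advanced_at_dx=advanced,
    )


def progressed_advanced(
    early_history: Mapping[int, Mapping[str, float]],
    models: Mapping[str, ProgressionModel],
    year: int,
) -> float:
    """Patients progressing to advanced disease in ``year`` from the early-
    stage cohorts of the previous ten diagnosis years.

    ``early_history`` maps diagnosis year to per-stage early counts; years
    missing from the mapping contribute nothing.
    """
    total = 0.0
    for d in range(1, 11):
        cohort = early_history.get(year - d)
        if not cohort:
            continue
        for stage, count in cohort.items():
            total += count * models[stage].interval_event_prob(d)
    return total


def lot_counts(advanced_total: float, params: CountryParams) -> dict[tuple[str, str], float]:
    """Treated patient counts by (histology, LOT) from an advanced-pool total:
    ``advanced * eligible% * histology share * LOT rate``."""
    if advanced_total < 0:
        raise DomainError(f"advanced_total must be >= 0, got {advanced_total}")
    eligible = advanced_total * params.pct_eligible / 100.0
    out = {}
    for h in HISTOLOGIES:
        pool = eligible * params.histology_share(h) / 100.0
        for lot in LOTS:
            out[(h, lot)] = pool * params.lot_rates[h][lot] / 100.0
    return out


# ---------------------------------------------------------------------------
# Country engine (vectorized over years; reused by the PSA)

HISTORY_YEARS = 10  # progression window


class CountryEngine:
    """Precomputed per-country arrays for fast repeated cascade evaluation.

    Holds the fitted trend per stratum, populations over the full year range
    (ten years before the first output year through the last output year),
    and baseline model rates.  ``incidence()`` re-evaluates only the
    projection block when the last-segment APCs are perturbed, which is what
    the probabilistic sensitivity analysis varies.
    """

    def __init__(self, country: str, fits: Sequence[JoinpointFit],
                 population: pd.DataFrame, out_years: tuple[int, int]):
        if not fits:
            raise ConfigurationError(f"no trend fits supplied for country {country}")
        self.country = country
        self.out_years = np.arange(out_years[0], out_years[1] + 1)
        self.years_all = np.arange(out_years[0] - HISTORY_YEARS, out_years[1] + 1)
        self.fits = list(fits)
        pop = population[population["country"] == country]
        pop_idx = pop.set_index(["sex", "age_group", "year"])["population"].sort_index()
        P, R0, flr, T = [], [], [], []
        for f in self.fits:
            try:
                P.append(pop_idx.loc[f.sex, f.age_cohort].reindex(self.years_all).to_numpy())
            except KeyError:
                raise KeyError(f"no population for stratum {country}/{f.sex}/{f.age_cohort}")
            R0.append(f.rate_at(self.years_all))
            flr.append(f.fitted_last_rate)
            T.append(f.last_year)
        self.pop = np.asarray(P, dtype=float)
        if np.isnan(self.pop).any():
            missing = self.years_all[np.isnan(self.pop).any(axis=0)]
            raise KeyError(f"population for {country} missing years {missing.tolist()}")
        self.rates0 = np.asarray(R0, dtype=float)
        self.fitted_last = np.asarray(flr, dtype=float)
        self.last_year = np.asarray(T, dtype=int)
        self.apc0 = np.array([f.last_segment.apc for f in self.fits])
        self.apc_se = np.array([f.last_segment.slope_se for f in self.fits])
        # horizon (years past each stratum's last data year; 0 within data)
        self.horizon = np.maximum(self.years_all[None, :] - self.last_year[:, None], 0)

    def incidence(self, apc_last: np.ndarray | None = None, scale: float = 1.0) -> np.ndarray:
        """Country-level incident counts per year of ``years_all``.

        ``apc_last`` (one value per stratum) replaces the fitted last-segment
        APC in the projection years only; fitted/backfilled in-sample rates
        are unchanged.
        """
        if apc_last is None:
            R = self.rates0
        else:
            growth = (1.0 + np.asarray(apc_last) / 100.0)[:, None] ** self.horizon
            R = np.where(self.horizon > 0, self.fitted_last[:, None] * growth, self.rates0)
        return scale * np.einsum("sy,sy->y", R, self.pop) / 1e5

    def stratum_counts(self, scale: float = 1.0) -> pd.DataFrame:
        """Tidy per-stratum incident counts over the full year range."""
        counts = scale * self.rates0 * self.pop / 1e5
        rows = []
        for f, c in zip(self.fits, counts):
            for year, v in zip(self.years_all, c):
                rows.append((self.country, f.sex, f.age_cohort, int(year), float(v)))
        return pd.DataFrame(rows, columns=["country", "sex", "age_group", "year", "count"])


def _cascade_arrays(
    incidence: np.ndarray,
    years_all: np.ndarray,
    params: CountryParams,
    prog_models: Mapping[str, ProgressionModel],
    survival_lag: bool = False,
    lag_months: float = 6.0,
) -> dict:
    """Vectorized cascade over a contiguous year range.

    Returns per-year arrays for the advanced pool and per (histology, LOT)
    counts; the first ``HISTORY_YEARS`` entries lack full progression history
    and are only used as history, never reported.
    """
    dist = redistribute_unknown_stage(params.stage_dist)
    p_IIIb = params.pct_IIIb_of_III / 100.0
    nsclc = incidence * params.pct_nsclc / 100.0
    early = {
        "I": nsclc * dist["I"] / 100.0,
        "II": nsclc * dist["II"] / 100.0,
        "IIIA": nsclc * dist["III"] / 100.0 * (1.0 - p_IIIb),
    }
    adv_dx = nsclc * (dist["IV"] / 100.0 + dist["III"] / 100.0 * p_IIIb)

    prog = np.zeros_like(incidence)
    for s, model in prog_models.items():
        conv = np.convolve(early[s], model.interval_probs())
        # conv[m] lands in year years_all[0] + m + 1
        m = np.arange(conv.size) + 1
        valid = m < incidence.size
        prog[m[valid]] += conv[valid]
    advanced = adv_dx + prog

    eligible = advanced * params.pct_eligible / 100.0
    cells = {}
    if survival_lag:
        mort = params.mortality_models()
    for h in HISTOLOGIES:
        pool = eligible * params.histology_share(h) / 100.0
        for lot in LOTS:
            base = pool * params.lot_rates[h][lot] / 100.0
            if survival_lag:
                s_lag = mort[h].survival_fraction(lag_months)
                shifted = np.zeros_like(base)
                shifted[1:] = base[:-1]
                base = s_lag * (0.5 * base + 0.5 * shifted)
            cells[(h, lot)] = base
    return {"nsclc": nsclc, "early": early, "advanced_at_dx": adv_dx,
            "progressed": prog, "advanced": advanced, "cells": cells}


@dataclass(frozen=True)
class PatientCountTable:
    """Deterministic PCM output: counts by country/year/histology/LOT.

    ``cells`` has columns country, year, histology, lot, count, count_rounded
    (nearest 100); ``totals()`` aggregates across histology.
    """

    cells: pd.DataFrame

    @staticmethod
    def round100(x):
        return np.round(np.asarray(x, dtype=float) / 100.0) * 100.0

    def totals(self) -> pd.DataFrame:
        # plain left-to-right accumulation in row order (pandas' grouped sum
        # is compensated, which would differ in the last ulp from a direct
        # histology-wise addition)
        acc: dict[tuple, float] = {}
        for row in self.cells.itertuples():
            key = (row.country, row.year, row.lot)
            acc[key] = acc.get(key, 0.0) + row.count
        t = pd.DataFrame([k + (v,) for k, v in acc.items()],
                         columns=["country", "year", "lot", "count"])
        t["count_rounded"] = self.round100(t["count"])
        return t

    def lookup(self, country: str, year: int, lot: str, rounded: bool = True) -> float:
        t = self.totals()
        row = t[(t["country"] == country) & (t["year"] == year) & (t["lot"] == lot)]
        if row.empty:
            raise KeyError((country, year, lot))
        return float(row["count_rounded" if rounded else "count"].iloc[0])


def build_engines(
    fits_by_country: Mapping[str, Sequence[JoinpointFit]],
    population: pd.DataFrame,
    years: tuple[int, int],
) -> dict[str, CountryEngine]:
    return {c: CountryEngine(c, fits, population, years)
            for c, fits in fits_by_country.items()}


def run_deterministic(
    fits_by_country: Mapping[str, Sequence[JoinpointFit]],
    population: pd.DataFrame,
    params_by_country: Mapping[str, CountryParams],
    years: tuple[int, int] = (2016, 2020),
    progression_shapes: Mapping[str, float] | None = None,
    survival_lag: bool = False,
    rate_scale: Mapping[str, float] | float = 1.0,
    include_first_lot: bool = False,
    engines: Mapping[str, CountryEngine] | None = None,
) -> PatientCountTable:
    """Run the full deterministic cascade for the requested output years.

    Progression history before each country's first registry year is implied
    by the fitted trend's backward extension (reverse compounding of the
    first segment's APC), so every output year has a complete ten-year early-
    stage history.
    """
    missing = [c for c in fits_by_country if c not in params_by_country]
    if missing:
        raise ConfigurationError(f"no CountryParams supplied for: {', '.join(missing)}")
    if engines is None:
        engines = build_engines(fits_by_country, population, years)
    rows = []
    lots = LOTS if include_first_lot else ("second", "third")
    for country, eng in engines.items():
        params = params_by_country[country]
        scale = rate_scale if np.isscalar(rate_scale) else rate_scale.get(country, 1.0)
        inc = eng.incidence(scale=scale)
        res = _cascade_arrays(inc, eng.years_all, params,
                              params.progression_models(progression_shapes),
                              survival_lag=survival_lag)
        out_idx = np.searchsorted(eng.years_all, eng.out_years)
        for h in HISTOLOGIES:
            for lot in lots:
                vals = res["cells"][(h, lot)][out_idx]
                for year, v in zip(eng.out_years, vals):
                    rows.append((country, int(year), h, lot, float(v)))
    cells = pd.DataFrame(rows, columns=["country", "year", "histology", "lot", "count"])
    cells["count_rounded"] = PatientCountTable.round100(cells["count"])
    return PatientCountTable(cells=cells)


def cagr_pct(start: float, end: float, years: int) -> float:
    """Compound annual growth rate in %: ``100 * ((end/start)**(1/years) - 1)``."""
    if start <= 0 or end <= 0 or years <= 0:
        raise DomainError("cagr_pct needs positive start, end and years")
    return 100.0 * ((end / start) ** (1.0 / years) - 1.0)
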