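"""Registry-like synthetic data with known ground truth.

Cancer registries publish crude incidence rates per 100,000 by sex and
five-year age cohort; national statistics offices publish smooth population
projections.  Neither source is redistributable, so this module generates
stand-ins with *known* generating parameters: piecewise log-linear incidence
trends (a constant annual percent change, APC, within each segment),
mean-preserving multiplicative lognormal observation noise, exact
geometric-growth population projections, and cumulative recurrence curves
drawn from a Weibull distribution.  Every generator takes an explicit seed
and is bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .progression import weibull_cdf
from .trends import IncidenceSeries

#: The ten age cohorts modeled (incidence below age 40 is treated as
#: negligible and left out of the model).
AGE_COHORTS = (
    "40-44", "45-49", "50-54", "55-59", "60-64",
    "65-69", "70-74", "75-79", "80-84", "85+",
)

SEXES = ("M", "F")


@dataclass(frozen=True)
class TrendSpec:
    """Ground truth for one stratum's incidence trend.

    ``segments`` is an ordered sequence of ``(start_year, apc_pct)`` pairs;
    the APC of a segment applies to every year-over-year step from its start
    year until the next segment begins.  The first segment must start at the
    first year of the series.

    ``noise_cv`` is the coefficient of variation of multiplicative lognormal
    observation noise (0 for noise-free series).
    """

    country: str
    sex: str
    age_cohort: str
    base_rate: float
    segments: tuple[tuple[int, float], ...]
    noise_cv: float = 0.0
    years: tuple[int, int] = (2000, 2012)

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple((int(y), float(a)) for y, a in self.segments))
        errs = []
        if self.sex not in SEXES:
            errs.append(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_cohort not in AGE_COHORTS:
            errs.append(f"age_cohort must be one of the ten modeled cohorts, got {self.age_cohort!r}")
        if not self.base_rate > 0:
            errs.append(f"base_rate must be > 0, got {self.base_rate}")
        if self.noise_cv < 0:
            errs.append(f"noise_cv must be >= 0, got {self.noise_cv}")
        y0, y1 = self.years
        if y1 < y0:
            errs.append(f"years range is empty: {self.years}")
        if not self.segments:
            errs.append("segments must be non-empty")
        else:
            starts = [s for s, _ in self.segments]
            if starts != sorted(set(starts)):
                errs.append(f"segment start_years must be strictly increasing, got {starts}")
            if starts[0] != y0:
                errs.append(f"first segment must start at the first year {y0}, got {starts[0]}")
            if any(s < y0 or s > y1 for s in starts):
                errs.append(f"segment start_years must lie within years {self.years}, got {starts}")
        if errs:
            raise ValidationError("; ".join(errs))

    def apc_at(self, year: int) -> float:
        """APC (%/yr) governing the step from ``year`` to ``year + 1``."""
        apc = self.segments[0][1]
        for start, a in self.segments:
            if start <= year:
                apc = a
        return apc

    def expected_rates(self) -> np.ndarray:
        """Noise-free rates: rate(t+1) = rate(t) * (1 + APC_active/100)."""
        y0, y1 = self.years
        rates = [self.base_rate]
        for year in range(y0, y1):
            rates.append(rates[-1] * (1.0 + self.apc_at(year) / 100.0))
        return np.asarray(rates, dtype=float)


def generate_registry_series(spec: TrendSpec, seed: int) -> IncidenceSeries:
    """Generate one stratum's incidence series from its trend spec.

    Noise is multiplicative lognormal with unit mean and coefficient of
    variation ``spec.noise_cv`` (registry rates are positive with roughly
    constant relative error), applied independently per year.
    """
    y0, y1 = spec.years
    years = np.arange(y0, y1 + 1)
    rates = spec.expected_rates()
    if spec.noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv ** 2))
        z = rng.standard_normal(rates.size)
        rates = rates * np.exp(sigma * z - 0.5 * sigma ** 2)
    return IncidenceSeries(
        country=spec.country, sex=spec.sex, age_cohort=spec.age_cohort,
        years=years, rates=rates,
    )


def generate_population(
    base_counts: Mapping[tuple, float],
    annual_growth: Mapping[tuple, float] | float,
    years: tuple[int, int],
) -> pd.DataFrame:
    """Deterministic geometric population projection per stratum.

    ``base_counts`` maps ``(country, sex, age_group)`` to persons in the first
    year; ``annual_growth`` gives %/yr per stratum (or one scalar for all).
    Returns a tidy frame with columns
    ``country, sex, age_group, year, population``.
    """
    y0, y1 = int(years[0]), int(years[1])
    if y1 < y0:
        raise ValidationError(f"years range is empty: {years}")
    if not base_counts:
        raise ValidationError("base_counts must be non-empty")
    rows = []
    yrs = np.arange(y0, y1 + 1)
    for key, base in base_counts.items():
        if base < 0:
            raise ValidationError(f"base count for stratum {key} is negative: {base}")
        g = annual_growth if np.isscalar(annual_growth) else annual_growth[key]
        pop = base * (1.0 + g / 100.0) ** (yrs - y0)
        country, sex, age = key
        for year, p in zip(yrs, pop):
            rows.append((country, sex, age, int(year), float(p)))
    return pd.DataFrame(rows, columns=["country", "sex", "age_group", "year", "population"])


@dataclass(frozen=True)
class RecurrenceCurveSpec:
    """Ground truth for a cumulative recurrence curve: Weibull scale ``alpha``
    (years), shape ``beta``, report timepoints (years), and additive Gaussian
    noise on the cumulative proportions (clipped to [0, 1])."""

    alpha: float
    beta: float
    timepoints: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0)
    noise_sd: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        errs = []
        if not self.alpha > 0:
            errs.append(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            errs.append(f"beta must be > 0, got {self.beta}")
        tp = self.timepoints
        if not tp or any(t <= 0 for t in tp) or list(tp) != sorted(set(tp)):
            errs.append(f"timepoints must be positive and strictly increasing, got {tp}")
        if self.noise_sd < 0:
            errs.append(f"noise_sd must be >= 0, got {self.noise_sd}")
        if errs:
            raise ValidationError("; ".join(errs))


def generate_recurrence_curve(spec: RecurrenceCurveSpec, seed: int) -> list[tuple[float, float]]:
    """Cumulative recurrence proportions at the spec's timepoints.

    Noise-free value at ``t`` is the Weibull CDF ``1 - exp(-(t/alpha)**beta)``;
    noisy values are clipped to [0, 1].
    """
    t = np.asarray(spec.timepoints)
    props = weibull_cdf(t, spec.alpha, spec.beta)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        props = np.clip(props + rng.normal(0.0, spec.noise_sd, props.size), 0.0, 1.0)
    return list(zip(t.tolist(), props.tolist()))


# ---------------------------------------------------------------------------
# CSV output (registry-extract-like dialect used throughout the package)

def incidence_frame(series: Sequence[IncidenceSeries]) -> pd.DataFrame:
    """Stack series into a tidy frame: country, sex, age_group, year, rate_per_100k."""
    rows = []
    for s in series:
        for year, rate in zip(s.years, s.rates):
            rows.append((s.country, s.sex, s.age_cohort, int(year), float(rate)))
    return pd.DataFrame(rows, columns=["country", "sex", "age_group", "year", "rate_per_100k"])


def write_incidence_csv(series: Sequence[IncidenceSeries], path) -> None:
    incidence_frame(series).to_csv(path, index=False)


def write_population_csv(population: pd.DataFrame, path) -> None:
    cols = ["country", "sex", "age_group", "year", "population"]
    population[cols].to_csv(path, index=False)


def read_incidence_csv(path) -> list[IncidenceSeries]:
    """Read an incidence CSV (written by :func:`write_incidence_csv`) back
    into per-stratum series objects."""
    df = pd.read_csv(path, comment="#")
    out = []
    for (country, sex, age), grp in df.groupby(["country", "sex", "age_group"], sort=False):
        grp = grp.sort_values("year")
        out.append(IncidenceSeries(
            country=country, sex=sex, age_cohort=age,
            years=grp["year"].to_numpy(int), rates=grp["rate_per_100k"].to_numpy(float),
        ))
    return out


def baseline_trend_specs(
    countries: Sequence[str],
    noise_cv: float | None = None,
    rate_scale: Mapping[str, float] | float = 1.0,
) -> list[TrendSpec]:
    """Trend specs for the bundled scenario: synthetic baseline rates with
    published last-segment APCs as the (single-segment) generating trend,
    over each country's registry coverage years."""
    from .datasets import load_apc_table, load_scenario_settings, load_synthetic_baseline

    apc = load_apc_table().set_index(["country", "sex", "age_group"])["apc_pct"]
    base = load_synthetic_baseline().set_index(["country", "sex", "age_group"])
    cov = load_scenario_settings()["registry_years"]
    if noise_cv is None:
        noise_cv = float(load_scenario_settings()["noise_cv"])
    specs = []
    for country in countries:
        y0, y1 = cov[country]
        scale = rate_scale if np.isscalar(rate_scale) else rate_scale.get(country, 1.0)
        for sex in SEXES:
            for cohort in AGE_COHORTS:
                key = (country, sex, cohort)
                specs.append(TrendSpec(
                    country=country, sex=sex, age_cohort=cohort,
                    base_rate=float(base.loc[key, "base_rate_per_100k"]) * float(scale),
                    segments=((y0, float(apc.loc[key])),),
                    noise_cv=noise_cv, years=(y0, y1),
                ))
    return specs


def baseline_population(countries: Sequence[str], years: tuple[int, int] = (1990, 2030)) -> pd.DataFrame:
    """Population projection for the bundled scenario.

    The synthetic baseline stores year-2000 populations and constant growth
    rates; the projection is extended backwards and forwards by the same
    geometric rule so the cascade's pre-2000 progression history has matching
    denominators.
    """
    from .datasets import load_synthetic_baseline

    df = load_synthetic_baseline()
    df = df[df["country"].isin(countries)]
    y0, y1 = years
    yrs = np.arange(y0, y1 + 1)
    rows = []
    for _, r in df.iterrows():
        pop = r["population_2000"] * (1.0 + r["pop_growth_pct"] / 100.0) ** (yrs - 2000)
        for year, p in zip(yrs, pop):
            rows.append((r["country"], r["sex"], r["age_group"], int(year), float(p)))
    return pd.DataFrame(rows, columns=["country", "sex", "age_group", "year", "population"])
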