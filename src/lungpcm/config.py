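"""Run configuration: loading, defaulting and whole-file validation.

A single YAML (or JSON) file drives the pipeline.  Validation is *complete*:
every problem in the file is collected and reported at once, so a run cannot
fail late on an error that was detectable from the configuration alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cascade import CountryParams
from .datasets import COUNTRIES, load_country_params_dict
from .exceptions import ConfigValidationError

_TOP_KEYS = {
    "countries", "years", "seed", "noise_cv", "incidence_csv", "population_csv",
    "trend", "psa", "country_params", "calibrate", "survival_lag", "out_dir",
}
_TREND_KEYS = {"max_joinpoints", "alpha", "n_perm"}
_PSA_KEYS = {"n_sims", "rel_halfwidth", "stage_ess", "vary_apc"}


@dataclass
class TrendSettings:
    max_joinpoints: int = 1
    alpha: float = 0.05
    n_perm: int = 499


@dataclass
class PSASettings:
    n_sims: int = 1000
    rel_halfwidth: float = 0.10
    stage_ess: float = 100.0
    vary_apc: bool = True


@dataclass
class RunConfig:
    """Validated run configuration with bundled defaults injected."""

    countries: list[str] = field(default_factory=lambda: list(COUNTRIES))
    years: tuple[int, int] = (2016, 2020)
    seed: int = 0
    noise_cv: float | None = None          # None -> bundled scenario default
    incidence_csv: str | None = None       # None -> generate bundled scenario
    population_csv: str | None = None
    trend: TrendSettings = field(default_factory=TrendSettings)
    psa: PSASettings = field(default_factory=PSASettings)
    country_params: dict[str, CountryParams] = field(default_factory=dict)
    calibrate: bool = True
    survival_lag: bool = False
    out_dir: str = "output"

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # output location does not affect results
        payload["country_params"] = {c: p.to_dict() if isinstance(p, CountryParams) else p
                                     for c, p in self.country_params.items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _merge_country_params(country: str, override: dict | None, errors: list[str]) -> CountryParams | None:
    """Bundled defaults for the country, with any override keys merged on top."""
    try:
        base = dict(load_country_params_dict(country))
    except KeyError:
        if not override:
            errors.append(f"country {country!r} has no bundled parameters and no "
                          "country_params override")
            return None
        base = {}
    merged = {**base, **(override or {})}
    try:
        params = CountryParams.from_dict(country, merged)
    except KeyError as e:
        errors.append(f"{country}: missing parameter {e}")
        return None
    except Exception as e:
        errors.append(str(e))
        return None
    return params


def load_and_validate_config(path) -> RunConfig:
    """Parse and validate a config file, raising one aggregated error."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    errors: list[str] = []

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")
    for sub, allowed in (("trend", _TREND_KEYS), ("psa", _PSA_KEYS)):
        bad = set(raw.get(sub) or {}) - allowed
        if bad:
            errors.append(f"unknown keys under {sub!r}: {sorted(bad)}")

    countries = raw.get("countries") or list(COUNTRIES)
    if not countries:
        errors.append("countries must be non-empty")

    years = tuple(raw.get("years") or (2016, 2020))
    if len(years) != 2 or years[1] < years[0]:
        errors.append(f"years must be [first, last] with first <= last, got {years}")
    elif not (2001 <= years[0] and years[1] <= 2030):
        errors.append(f"forecast years must lie within [2001, 2030], got {years}")

    for key in ("incidence_csv", "population_csv"):
        p = raw.get(key)
        if p is not None and not Path(p).exists():
            errors.append(f"{key} file does not exist: {p}")

    overrides = raw.get("country_params") or {}
    bad_override = set(overrides) - set(countries)
    if bad_override:
        errors.append(f"country_params given for countries not in the run: {sorted(bad_override)}")
    params = {}
    for c in countries:
        p = _merge_country_params(c, overrides.get(c), errors)
        if p is not None:
            params[c] = p

    trend = TrendSettings(**{k: v for k, v in (raw.get("trend") or {}).items()
                             if k in _TREND_KEYS})
    psa = PSASettings(**{k: v for k, v in (raw.get("psa") or {}).items()
                         if k in _PSA_KEYS})
    if trend.max_joinpoints not in (0, 1, 2):
        errors.append(f"trend.max_joinpoints must be 0, 1 or 2, got {trend.max_joinpoints}")
    if trend.max_joinpoints > 0 and trend.n_perm < 99:
        errors.append(f"trend.n_perm must be >= 99, got {trend.n_perm}")
    if psa.n_sims < 1:
        errors.append(f"psa.n_sims must be >= 1, got {psa.n_sims}")

    if errors:
        raise ConfigValidationError(errors)

    return RunConfig(
        countries=list(countries), years=(int(years[0]), int(years[1])),
        seed=int(raw.get("seed", 0)), noise_cv=raw.get("noise_cv"),
        incidence_csv=raw.get("incidence_csv"), population_csv=raw.get("population_csv"),
        trend=trend, psa=psa, country_params=params,
        calibrate=bool(raw.get("calibrate", True)),
        survival_lag=bool(raw.get("survival_lag", False)),
        out_dir=str(raw.get("out_dir", "output")),
    )
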