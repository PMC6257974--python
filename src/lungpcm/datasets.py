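"""Loaders for the parameter tables bundled with the package.

Four fixtures ship with the package under ``lungpcm/data``:

``apc_last_segment.csv``
    Published annual-percent-change (APC) estimates for the last joinpoint
    segment of lung cancer incidence, by country, sex and age cohort.
``country_params.yaml``
    Published country-level model parameters (morphology, histology, stage at
    diagnosis, five-year recurrence, median OS, eligibility and LOT rates).
``published_projections.csv``
    Published second/third-line patient-count projections (deterministic and
    probabilistic) used as calibration anchors and reference values.
``synthetic_baseline.csv``
    Synthetic baseline demographics (rates and populations by stratum) for the
    bundled scenario; not registry data.
``scenario.yaml``
    Registry coverage years per country plus published validation figures.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd
import yaml

COUNTRIES = ("France", "Germany", "Italy", "Spain")


def _data_path(name: str):
    return resources.files("lungpcm.data").joinpath(name)


@functools.lru_cache(maxsize=None)
def load_apc_table() -> pd.DataFrame:
    """Published last-segment APC estimates, one row per country/sex/age cohort."""
    with resources.as_file(_data_path("apc_last_segment.csv")) as p:
        return pd.read_csv(p, comment="#")


@functools.lru_cache(maxsize=None)
def _raw_country_params() -> dict:
    return yaml.safe_load(_data_path("country_params.yaml").read_text())


def load_country_params_dict(country: str | None = None) -> dict:
    """Raw published parameter dictionaries keyed by country."""
    raw = _raw_country_params()
    if country is not None:
        if country not in raw:
            raise KeyError(f"no bundled parameters for country {country!r}")
        return raw[country]
    return raw


@functools.lru_cache(maxsize=None)
def load_published_projections() -> pd.DataFrame:
    """Published deterministic and probabilistic LOT patient-count projections."""
    with resources.as_file(_data_path("published_projections.csv")) as p:
        return pd.read_csv(p, comment="#")


@functools.lru_cache(maxsize=None)
def load_synthetic_baseline() -> pd.DataFrame:
    """Synthetic per-stratum baseline rates, populations and growth rates."""
    with resources.as_file(_data_path("synthetic_baseline.csv")) as p:
        return pd.read_csv(p, comment="#")


@functools.lru_cache(maxsize=None)
def load_scenario_settings() -> dict:
    """Registry coverage years and published validation figures."""
    return yaml.safe_load(_data_path("scenario.yaml").read_text())
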