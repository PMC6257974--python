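"""Probabilistic sensitivity analysis (PSA) over the deterministic cascade.

Each of ``n_sims`` simulations draws one full parameter set — proportions
from beta distributions (method of moments on a mean and 95% CI), the stage-
at-diagnosis vector from a Dirichlet distribution, last-segment APCs from
normal distributions centred on the fitted estimates, and time-to-event
anchors (five-year recurrence, median OS) whose draws are propagated through
Weibull recalibration — then reruns the cascade.  Per output cell the mean
and the 2.5th/97.5th percentiles of the simulated counts are reported.

Published parameter tables carry no input CIs, so proportion CIs default to
a +/-10% relative half-width and the Dirichlet effective sample size to 100;
both are configuration fields, not constants.  Simulations use independent
RNG substreams spawned from the master seed, so results do not depend on
execution order.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cascade import (EARLY_STAGES, HISTOLOGIES, LOTS, CountryEngine, CountryParams,
                      PatientCountTable, _cascade_arrays, build_engines)
from .exceptions import DomainError, LungPCMError, ValidationError

_Z95 = 3.92  # width of a 95% normal CI in SE units (2 * 1.96)


def beta_from_mean_ci(mean: float, ci_low: float, ci_high: float):
    """Beta shape parameters (a, b) from a mean and 95% CI by method of
    moments: ``SE = (ci_high - ci_low)/3.92``, ``nu = mean(1-mean)/SE^2 - 1``,
    ``a = mean*nu``, ``b = (1-mean)*nu``.

    Returns ``None`` (a point mass at the mean) for a degenerate CI, or —
    with a warning — when the implied variance is too large for a beta
    distribution (``nu <= 0``).
    """
    if not (0.0 < mean < 1.0):
        raise DomainError(f"mean must be in (0, 1), got {mean}")
    if ci_low > ci_high:
        raise ValidationError(f"ci_low {ci_low} > ci_high {ci_high}")
    if not (ci_low <= mean <= ci_high):
        raise ValidationError(f"mean {mean} outside CI [{ci_low}, {ci_high}]")
    se = (ci_high - ci_low) / _Z95
    if se == 0.0:
        return None
    nu = mean * (1.0 - mean) / se ** 2 - 1.0
    if nu <= 0.0:
        _warnings.warn(
            f"CI [{ci_low}, {ci_high}] too wide for a beta at mean {mean}; "
            "falling back to a point mass", stacklevel=2)
        return None
    return mean * nu, (1.0 - mean) * nu


def dirichlet_from_proportions(props: Sequence[float], ess: float) -> np.ndarray:
    """Dirichlet concentration vector ``props * ess`` (draws then have
    expected value ``props``)."""
    p = np.asarray(props, dtype=float)
    if np.any(p < 0):
        raise DomainError(f"proportions must be >= 0, got {p}")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions must sum to 1, got {p.sum()!r}")
    if ess <= 0:
        raise DomainError(f"effective sample size must be > 0, got {ess}")
    return p * ess


@dataclass(frozen=True)
class PSAConfig:
    """PSA settings.

    ``rel_halfwidth`` is the relative half-width of the implied 95% CI on
    every proportion and on median OS (0 disables all parameter variation);
    ``stage_ess`` is the Dirichlet effective sample size for the stage
    vector; ``vary_apc`` toggles normal sampling of last-segment APCs using
    the trend fits' standard errors.
    """

    n_sims: int = 1000
    seed: int = 0
    rel_halfwidth: float = 0.10
    stage_ess: float = 100.0
    vary_apc: bool = True
    max_failure_rate: float = 0.05

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValidationError(f"n_sims must be >= 1, got {self.n_sims}")
        if self.rel_halfwidth < 0:
            raise ValidationError(f"rel_halfwidth must be >= 0, got {self.rel_halfwidth}")
        if self.stage_ess <= 0:
            raise ValidationError(f"stage_ess must be > 0, got {self.stage_ess}")

    @classmethod
    def zero_variance(cls, n_sims: int = 1, seed: int = 0) -> "PSAConfig":
        return cls(n_sims=n_sims, seed=seed, rel_halfwidth=0.0, vary_apc=False)


def _draw_proportion(rng, mean: float, rel_halfwidth: float) -> float:
    """One beta draw for a proportion with a +/-rel_halfwidth relative 95% CI
    (clipped into (0, 1))."""
    if rel_halfwidth == 0.0 or mean <= 0.0 or mean >= 1.0:
        return mean
    lo = max(mean * (1.0 - rel_halfwidth), 1e-9)
    hi = min(mean * (1.0 + rel_halfwidth), 1.0 - 1e-9)
    ab = beta_from_mean_ci(mean, lo, hi)
    if ab is None:
        return mean
    return float(rng.beta(*ab))


def _draw_positive(rng, mean: float, rel_halfwidth: float) -> float:
    """Normal draw for a positive quantity (median OS), truncated at a small
    positive floor; SE set so the 95% CI half-width is relative."""
    if rel_halfwidth == 0.0:
        return mean
    se = mean * rel_halfwidth / 1.96
    return float(max(rng.normal(mean, se), 0.05 * mean))


def sample_parameter_set(
    params: CountryParams,
    config: PSAConfig,
    rng: np.random.Generator,
) -> CountryParams:
    """Draw one country parameter set from the PSA distributions.

    With all variances zero the deterministic set is returned unchanged.
    LOT-rate draws are independent; draws violating the third <= second <=
    first ordering (vanishingly rare at the default CI widths) surface as
    validation errors and are dropped by :func:`run_psa`.
    """
    w = config.rel_halfwidth
    if w == 0.0:
        return params

    stage_labels = ["I", "II", "III", "IV", "unknown"]
    props = np.array([params.stage_dist[s] for s in stage_labels]) / 100.0
    conc = dirichlet_from_proportions(props / props.sum(), config.stage_ess)
    stage_draw = rng.dirichlet(conc) * 100.0

    sq = _draw_proportion(rng, params.pct_squamous / 100.0, w) * 100.0
    eligible = _draw_proportion(rng, params.pct_eligible / 100.0, w) * 100.0
    lot = {h: {l: _draw_proportion(rng, params.lot_rates[h][l] / 100.0, w) * 100.0
               for l in LOTS}
           for h in HISTOLOGIES}
    return replace(
        params,
        pct_nsclc=_draw_proportion(rng, params.pct_nsclc / 100.0, w) * 100.0,
        pct_squamous=sq, pct_nonsquamous=100.0 - sq,
        stage_dist=dict(zip(stage_labels, stage_draw)),
        pct_IIIb_of_III=_draw_proportion(rng, params.pct_IIIb_of_III / 100.0, w) * 100.0,
        recurrence_5yr={s: _draw_proportion(rng, params.recurrence_5yr[s] / 100.0, w) * 100.0
                        for s in EARLY_STAGES},
        median_os_months={h: _draw_positive(rng, params.median_os_months[h], w)
                          for h in HISTOLOGIES},
        pct_bsc=100.0 - eligible, pct_eligible=eligible,
        lot_rates=lot,
    )


def _sample_apcs(engine: CountryEngine, config: PSAConfig, rng) -> np.ndarray | None:
    """Normal draws of the last-segment APC per stratum (delta-method SE from
    the slope SE); ``None`` leaves the fitted APCs untouched."""
    if not config.vary_apc:
        return None
    se_apc = (100.0 + engine.apc0) * engine.apc_se  # d/ds 100(e^s - 1) = 100 e^s
    apc = rng.normal(engine.apc0, se_apc)
    return np.maximum(apc, -99.0)


@dataclass(frozen=True)
class ProbabilisticCounts:
    """PSA summary per country/year/LOT: mean and 95% percentile interval,
    plus the simulation count actually used and the number of dropped
    (failed) simulations."""

    table: pd.DataFrame
    n_sims: int
    n_failures: int
    seed: int
    draws: np.ndarray | None = None  # (n_ok, country, year, lot) when kept

    def lookup(self, country: str, year: int, lot: str) -> tuple[float, float, float]:
        t = self.table
        row = t[(t["country"] == country) & (t["year"] == year) & (t["lot"] == lot)]
        if row.empty:
            raise KeyError((country, year, lot))
        r = row.iloc[0]
        return float(r["mean"]), float(r["ci_low"]), float(r["ci_high"])


def run_psa(
    fits_by_country: Mapping[str, Sequence],
    population: pd.DataFrame,
    params_by_country: Mapping[str, CountryParams],
    config: PSAConfig,
    years: tuple[int, int] = (2016, 2020),
    progression_shapes: Mapping[str, float] | None = None,
    survival_lag: bool = False,
    rate_scale: Mapping[str, float] | float = 1.0,
    engines: Mapping[str, CountryEngine] | None = None,
    keep_draws: bool = False,
) -> ProbabilisticCounts:
    """Monte Carlo propagation of parameter uncertainty through the cascade.

    Runs ``config.n_sims`` simulations; per (country, year, LOT) cell returns
    the simulation mean and the 2.5/97.5 percentiles.  Failed simulations are
    dropped and counted; more than ``config.max_failure_rate`` failures is a
    run-level error.
    """
    if engines is None:
        engines = build_engines(fits_by_country, population, years)
    countries = list(engines)
    out_years = engines[countries[0]].out_years
    lots = ("second", "third")
    streams = np.random.SeedSequence(config.seed).spawn(config.n_sims)

    sims = np.full((config.n_sims, len(countries), out_years.size, len(lots)), np.nan)
    n_fail = 0
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        try:
            for ci, country in enumerate(countries):
                eng = engines[country]
                draw = sample_parameter_set(params_by_country[country], config, rng)
                apcs = _sample_apcs(eng, config, rng)
                scale = rate_scale if np.isscalar(rate_scale) else rate_scale.get(country, 1.0)
                inc = eng.incidence(apc_last=apcs, scale=scale)
                res = _cascade_arrays(inc, eng.years_all, draw,
                                      draw.progression_models(progression_shapes),
                                      survival_lag=survival_lag)
                out_idx = np.searchsorted(eng.years_all, eng.out_years)
                for li, lot in enumerate(lots):
                    total = sum(res["cells"][(h, lot)] for h in HISTOLOGIES)
                    sims[i, ci, :, li] = total[out_idx]
        except LungPCMError:
            sims[i] = np.nan
            n_fail += 1

    if n_fail > config.max_failure_rate * config.n_sims:
        raise LungPCMError(
            f"{n_fail}/{config.n_sims} PSA simulations failed "
            f"(> {config.max_failure_rate:.0%} allowed)")

    ok = ~np.isnan(sims[:, 0, 0, 0])
    good = sims[ok]
    mean = good.mean(axis=0)
    lo, hi = np.percentile(good, [2.5, 97.5], axis=0)
    rows = []
    for ci, country in enumerate(countries):
        for yi, year in enumerate(out_years):
            for li, lot in enumerate(lots):
                rows.append((country, int(year), lot,
                             float(mean[ci, yi, li]),
                             float(lo[ci, yi, li]), float(hi[ci, yi, li])))
    table = pd.DataFrame(rows, columns=["country", "year", "lot", "mean", "ci_low", "ci_high"])
    return ProbabilisticCounts(table=table, n_sims=int(ok.sum()), n_failures=n_fail,
                               seed=config.seed, draws=good if keep_draws else None)
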