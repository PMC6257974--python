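"""Segmented log-linear ("joinpoint") incidence trend analysis.

Incidence rates are modeled on the natural-log scale as continuous piecewise
linear functions of calendar year.  Each segment's slope ``b`` maps to an
annual percent change ``APC = 100 * (exp(b) - 1)``.  The number of joinpoints
is chosen by a sequential permutation test (the standard procedure of the
change-point trend software used in registry analyses): test k vs k+1
joinpoints by refitting permuted residuals of the smaller model, with a
Bonferroni correction across the sequence of tests.  Projection compounds the
last segment's APC forward from the model-fitted rate at the last data year,
regardless of the segment's statistical significance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, InsufficientDataError, ValidationError

_SSE_TOL = 1e-12  # relative: below this the model is treated as an exact fit


@dataclass(frozen=True)
class IncidenceSeries:
    """Observed incidence rates (per 100,000) for one country/sex/age stratum."""

    country: str
    sex: str
    age_cohort: str
    years: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "rates", rates)
        if years.shape != rates.shape or years.ndim != 1:
            raise ValidationError("years and rates must be 1-D arrays of equal length")
        if years.size and np.any(np.diff(years) <= 0):
            raise ValidationError("years must be strictly increasing")

    @property
    def has_gaps(self) -> bool:
        return bool(self.years.size > 1 and np.any(np.diff(self.years) > 1))

    def __len__(self):
        return self.years.size


@dataclass(frozen=True)
class SegmentEstimate:
    """One segment of a joinpoint fit: slope on the log scale, its APC, and
    Wald-style inference for the slope."""

    start_year: int
    end_year: int
    slope: float
    slope_se: float
    apc: float
    apc_ci_low: float
    apc_ci_high: float
    p_value: float


@dataclass(frozen=True)
class JoinpointFit:
    """A fitted segmented log-linear trend for one stratum."""

    country: str
    sex: str
    age_cohort: str
    years: np.ndarray
    joinpoint_years: tuple[int, ...]
    coef: np.ndarray           # (intercept, slope, hinge increments...) on log scale
    segments: tuple[SegmentEstimate, ...]
    fitted_last_rate: float
    residual_sse: float
    warnings: tuple[str, ...] = ()

    @property
    def n_joinpoints(self) -> int:
        return len(self.joinpoint_years)

    @property
    def last_segment(self) -> SegmentEstimate:
        return self.segments[-1]

    @property
    def first_segment(self) -> SegmentEstimate:
        return self.segments[0]

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    def rate_at(self, years) -> np.ndarray:
        """Model rate at arbitrary years.

        Inside the data range this evaluates the fitted piecewise-linear
        log-rate; outside it extends the first/last segment's line, which is
        identical to compounding that segment's APC (backwards before the
        first data year, forwards after the last)."""
        y = np.atleast_1d(np.asarray(years, dtype=float))
        X = _design(y, self.joinpoint_years)
        out = np.exp(X @ self.coef)
        return out if np.ndim(years) else float(out[0])

    def fitted_rates(self) -> np.ndarray:
        return self.rate_at(self.years)


# ---------------------------------------------------------------------------
# Elementary fits

def fit_loglinear(series: IncidenceSeries) -> tuple[float, float, float]:
    """OLS of ln(rate) on calendar year: returns (slope, intercept, slope_SE)."""
    _check_fittable(series)
    res = stats.linregress(series.years.astype(float), np.log(series.rates))
    se = 0.0 if not np.isfinite(res.stderr) else float(res.stderr)
    # linregress reports tiny floating noise as stderr for exact fits; snap it
    if se < 1e-8 * max(1.0, abs(res.slope)):
        se = 0.0
    return float(res.slope), float(res.intercept), se


def apc_from_slope(slope: float) -> float:
    """APC (%) from a log-scale per-year slope: 100 * (exp(slope) - 1)."""
    if not np.isfinite(slope):
        raise DomainError(f"slope must be finite, got {slope}")
    return 100.0 * math.expm1(slope)


def slope_from_apc(apc: float) -> float:
    """Inverse of :func:`apc_from_slope`."""
    if not np.isfinite(apc) or apc <= -100.0:
        raise DomainError(f"APC must be finite and > -100, got {apc}")
    return math.log1p(apc / 100.0)


def _check_fittable(series: IncidenceSeries) -> None:
    if len(series) < 3:
        raise InsufficientDataError(
            f"need >= 3 observations to fit a trend, got {len(series)} "
            f"({series.country}/{series.sex}/{series.age_cohort})")
    if np.any(series.rates <= 0):
        raise DomainError("all rates must be > 0 (log-linear model)")


# ---------------------------------------------------------------------------
# Segmented regression machinery

def _design(years: np.ndarray, taus: Sequence[int]) -> np.ndarray:
    """Design matrix for a continuous piecewise-linear model with hinges at taus."""
    y = np.asarray(years, dtype=float)
    cols = [np.ones_like(y), y]
    for tau in taus:
        cols.append(np.maximum(y - tau, 0.0))
    return np.column_stack(cols)


def _fit_ols(X: np.ndarray, logy: np.ndarray):
    coef, *_ = np.linalg.lstsq(X, logy, rcond=None)
    resid = logy - X @ coef
    return coef, resid, float(resid @ resid)


def _candidate_taus(years: np.ndarray, k: int) -> list[tuple[int, ...]]:
    """All valid joinpoint placements: joinpoints sit at observed years with at
    least 2 observations in each segment's interior (joinpoints excluded)."""
    n = years.size
    if k == 0:
        return [()]
    idx = range(n)
    out = []
    for combo in itertools.combinations(idx, k):
        bounds = (-1,) + combo + (n,)
        # interior count of segment j = obs strictly between its boundary joinpoints
        if all(bounds[j + 1] - bounds[j] - 1 >= 2 for j in range(len(bounds) - 1)):
            out.append(tuple(int(years[i]) for i in combo))
    return out


def _best_segmented(years: np.ndarray, logy: np.ndarray, k: int):
    """Exhaustive grid search over joinpoint placements for a k-joinpoint model.

    Ties in SSE are broken toward the earlier joinpoint years (candidates are
    enumerated in increasing year order, and strict improvement is required)."""
    best = None
    for taus in _candidate_taus(years, k):
        X = _design(years, taus)
        coef, resid, sse = _fit_ols(X, logy)
        if best is None or sse < best[2] - 1e-14 * max(1.0, best[2]):
            best = (taus, coef, sse)
    if best is None:
        raise InsufficientDataError(f"series too short for {k} joinpoint(s)")
    return best


def _segment_inference(years, taus, coef, sse, conf_level=0.95):
    """Per-segment slope, SE, APC with CI and p-value from the joint OLS fit."""
    n = years.size
    p = 2 + len(taus)
    df = max(n - p, 0)
    X = _design(years, taus)
    # QR-based inverse: calendar-year designs are ill-conditioned for X'X
    Q, R = np.linalg.qr(X)
    Rinv = np.linalg.solve(R, np.eye(p))
    XtX_inv = Rinv @ Rinv.T
    sigma2 = sse / df if df > 0 else 0.0
    if sse <= _SSE_TOL:  # exact fit: no residual variance
        sigma2 = 0.0
    cov = sigma2 * XtX_inv
    bounds = [int(years[0])] + list(taus) + [int(years[-1])]
    segs = []
    for j in range(len(taus) + 1):
        sel = np.zeros(p)
        sel[1:2 + j] = 1.0  # slope_j = b1 + sum of hinge increments up to j
        slope = float(sel @ coef)
        var = float(sel @ cov @ sel)
        se = math.sqrt(max(var, 0.0))
        if se > 0 and df > 0:
            tcrit = stats.t.ppf(0.5 + conf_level / 2.0, df)
            lo, hi = slope - tcrit * se, slope + tcrit * se
            tstat = slope / se
            pval = float(2.0 * stats.t.sf(abs(tstat), df))
        else:
            lo = hi = slope
            pval = 0.0 if abs(slope) > 0 else 1.0
        segs.append(SegmentEstimate(
            start_year=bounds[j], end_year=bounds[j + 1],
            slope=slope, slope_se=se,
            apc=apc_from_slope(slope),
            apc_ci_low=apc_from_slope(lo), apc_ci_high=apc_from_slope(hi),
            p_value=pval,
        ))
    return tuple(segs)


def _min_points_for(k: int) -> int:
    # k joinpoints, each segment needs >= 2 interior obs
    return 3 * k + 2 if k > 0 else 3


def _sse_min_over_models(Y: np.ndarray, projectors: list[np.ndarray]) -> np.ndarray:
    """Row-wise minimum SSE over candidate models.

    ``Y`` is (n_perm, n); each projector is the residual-maker M = I - H of
    one candidate design.  SSE = ||M y||^2."""
    best = None
    for M in projectors:
        E = Y @ M  # M symmetric: rows are (M y)^T
        sse = np.einsum("ij,ij->i", E, E)
        best = sse if best is None else np.minimum(best, sse)
    return best


def _residual_makers(years: np.ndarray, k: int) -> list[np.ndarray]:
    n = years.size
    mats = []
    for taus in _candidate_taus(years, k):
        X = _design(years, taus)
        Q, _ = np.linalg.qr(X)
        mats.append(np.eye(n) - Q @ Q.T)
    return mats


def _permutation_pvalue(years, logy, k0, n_perm, rng) -> float:
    """P-value of the test of k0 vs k0+1 joinpoints.

    Residuals of the best-fitting k0 model are permuted, added back to its
    fitted values, and the SSE-improvement statistic is recomputed for each
    permutation; the p-value is the (add-one) upper tail proportion."""
    taus0, coef0, sse0 = _best_segmented(years, logy, k0)
    _, _, sse1 = _best_segmented(years, logy, k0 + 1)
    scale = max(float(np.var(logy) * years.size), 1e-30)
    if sse0 <= _SSE_TOL * scale:
        return 1.0  # smaller model already exact: no evidence for more joinpoints
    t_obs = (sse0 - sse1) / sse1 if sse1 > 0 else np.inf

    fitted0 = _design(years, taus0) @ coef0
    resid0 = logy - fitted0
    R = rng.permuted(np.tile(resid0, (n_perm, 1)), axis=1)
    Y = fitted0[None, :] + R
    m0 = _residual_makers(years, k0)
    m1 = _residual_makers(years, k0 + 1)
    sse0_p = _sse_min_over_models(Y, m0)
    sse1_p = _sse_min_over_models(Y, m1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(sse1_p > 0, (sse0_p - sse1_p) / sse1_p, np.inf)
    return float((1 + np.sum(t_perm >= t_obs)) / (n_perm + 1))


def select_joinpoints(
    series: IncidenceSeries,
    max_joinpoints: int = 1,
    alpha: float = 0.05,
    n_perm: int = 499,
    seed: int = 0,
) -> JoinpointFit:
    """Fit a segmented log-linear trend, choosing the number of joinpoints.

    Starting from zero joinpoints, the k vs k+1 comparison is repeated while
    the permutation test rejects at level ``alpha / max_joinpoints``
    (Bonferroni across the selection sequence).  Joinpoints are constrained to
    observed years with at least two observations in each segment interior.
    Returns the selected model with per-segment APC inference.
    """
    _check_fittable(series)
    if max_joinpoints not in (0, 1, 2):
        raise ValidationError(f"max_joinpoints must be 0, 1 or 2, got {max_joinpoints}")
    if max_joinpoints > 0 and n_perm < 99:
        raise ValidationError(f"n_perm must be >= 99, got {n_perm}")

    warnings: list[str] = []
    n = len(series)
    while max_joinpoints > 0 and n < _min_points_for(max_joinpoints):
        warnings.append(
            f"series has {n} points, too short for {max_joinpoints} joinpoint(s); "
            f"reduced to {max_joinpoints - 1}")
        max_joinpoints -= 1

    years = series.years
    logy = np.log(series.rates)
    rng = np.random.default_rng(seed)

    k = 0
    level = alpha / max_joinpoints if max_joinpoints > 0 else alpha
    while k < max_joinpoints:
        pval = _permutation_pvalue(years, logy, k, n_perm, rng)
        if pval < level:
            k += 1
        else:
            break

    taus, coef, sse = _best_segmented(years, logy, k)
    segments = _segment_inference(years, taus, coef, sse)
    fitted_last = float(np.exp(_design(years[-1:], taus) @ coef)[0])
    return JoinpointFit(
        country=series.country, sex=series.sex, age_cohort=series.age_cohort,
        years=years.copy(), joinpoint_years=taus, coef=np.asarray(coef),
        segments=segments, fitted_last_rate=fitted_last, residual_sse=sse,
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# Projection and counts

def project_rates(fit: JoinpointFit, horizon_years: int) -> np.ndarray:
    """Rates for the ``horizon_years`` years after the last data year:
    ``rate(T+h) = fitted_last_rate * (1 + APC_last/100)**h``.

    The last segment's APC is applied regardless of statistical significance.
    """
    if horizon_years < 1:
        raise DomainError(f"horizon_years must be >= 1, got {horizon_years}")
    apc = fit.last_segment.apc
    if apc <= -100.0:
        raise DomainError(f"last-segment APC {apc} <= -100 gives non-positive rates")
    h = np.arange(1, horizon_years + 1)
    return fit.fitted_last_rate * (1.0 + apc / 100.0) ** h


def incident_counts(rates: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Incident case counts: ``count = rate/100000 * population``, matched by
    (country, sex, age_group, year).

    ``rates`` must have a ``rate_per_100k`` column; a stratum-year present in
    ``rates`` but missing from ``population`` raises a KeyError naming it.
    """
    keys = ["country", "sex", "age_group", "year"]
    merged = rates.merge(population[keys + ["population"]], on=keys, how="left")
    missing = merged[merged["population"].isna()]
    if len(missing):
        first = missing.iloc[0]
        raise KeyError(
            f"no population for stratum {first['country']}/{first['sex']}/"
            f"{first['age_group']} year {int(first['year'])} "
            f"({len(missing)} missing stratum-years)")
    merged["count"] = merged["rate_per_100k"] / 1e5 * merged["population"]
    return merged[keys + ["count"]]


def fit_summary_frame(fits: Sequence[JoinpointFit]) -> pd.DataFrame:
    """Tabular last-segment summary of joinpoint fits (one row per stratum),
    with a significance marker at p < 0.05."""
    rows = []
    for f in fits:
        seg = f.last_segment
        rows.append({
            "country": f.country, "sex": f.sex, "age_group": f.age_cohort,
            "n_joinpoints": f.n_joinpoints,
            "last_segment_APC": seg.apc,
            "APC_CI_low": seg.apc_ci_low, "APC_CI_high": seg.apc_ci_high,
            "p_value": seg.p_value,
            "significant": seg.p_value < 0.05,
            "fitted_last_rate": f.fitted_last_rate,
        })
    return pd.DataFrame(rows)
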