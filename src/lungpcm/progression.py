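"""Weibull time-to-event models for disease progression and mortality.

Early-stage (I, II, IIIA) NSCLC patients may relapse with distant (advanced)
disease; published five-year cumulative recurrence proportions anchor a
Weibull model per stage.  The convention used throughout is

    F(t) = 1 - exp(-(t / alpha)**beta)

with *scale* ``alpha`` (time units) and *shape* ``beta`` (dimensionless;
beta = 1 is the exponential special case, beta > 1 accelerating failure).
The scale is solved in closed form from the anchor proportion; the shape is
either fit to a published cumulative curve by least squares or defaults to 1.
Progression is truncated at a 10-year window: patients without recurrence by
then are considered cured.  Post-progression mortality uses the same Weibull
machinery anchored on median overall survival in months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .exceptions import DomainError, InsufficientDataError, ValidationError

SHAPE_BOUNDS = (0.2, 5.0)


def weibull_cdf(t, alpha: float, beta: float):
    """Cumulative event probability F(t) = 1 - exp(-(t/alpha)**beta)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    out = -np.expm1(-np.power(t / alpha, beta))
    return float(out) if out.ndim == 0 else out


def calibrate_weibull_scale(p_t: float, t: float, beta: float) -> float:
    """Scale ``alpha`` such that F(t; alpha, beta) = p_t, in closed form:
    ``alpha = t / (-ln(1 - p_t))**(1/beta)``."""
    if not (0.0 < p_t < 1.0):
        raise DomainError(f"anchor proportion must be in (0, 1), got {p_t}")
    if t <= 0:
        raise DomainError(f"anchor time must be > 0, got {t}")
    if beta <= 0:
        raise DomainError(f"shape must be > 0, got {beta}")
    return t / (-math.log1p(-p_t)) ** (1.0 / beta)


def fit_weibull_shape(
    curve: Sequence[tuple[float, float]],
    p5: float,
    anchor_t: float = 5.0,
    bounds: tuple[float, float] = SHAPE_BOUNDS,
) -> float:
    """Least-squares shape fit to a cumulative event curve.

    At each candidate shape the scale is re-solved from the anchor
    (``F(anchor_t) = p5``) so the fitted curve always passes through the
    anchor; the returned shape minimizes the sum of squared differences to
    the supplied ``(time, cumulative proportion)`` points over a bounded 1-D
    search.
    """
    pts = [(float(t), float(p)) for t, p in curve if t > 0 and 0.0 < p < 1.0]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need >= 3 curve points with t > 0 and proportion in (0, 1), got {len(pts)}")
    t = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(y, y[0]):
        raise ValidationError("degenerate curve: all proportions equal")

    def sse(beta: float) -> float:
        alpha = calibrate_weibull_scale(p5, anchor_t, beta)
        return float(np.sum((weibull_cdf(t, alpha, beta) - y) ** 2))

    res = optimize.minimize_scalar(sse, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


@dataclass(frozen=True)
class ProgressionModel:
    """Early-to-advanced progression for one early stage, truncated at
    ``window`` years (cure beyond the window)."""

    stage: str
    alpha: float
    beta: float
    p5: float
    window: int = 10

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError(f"alpha and beta must be > 0, got {self.alpha}, {self.beta}")

    @classmethod
    def from_five_year_recurrence(cls, stage: str, p5: float, beta: float = 1.0,
                                  window: int = 10) -> "ProgressionModel":
        """Calibrate the scale from a five-year cumulative recurrence
        proportion ``p5`` (0-1) at the given shape."""
        alpha = calibrate_weibull_scale(p5, 5.0, beta)
        return cls(stage=stage, alpha=alpha, beta=beta, p5=p5, window=window)

    def cdf(self, t) -> float:
        return weibull_cdf(t, self.alpha, self.beta)

    def interval_event_prob(self, d: int) -> float:
        """Probability of progression in year ``d`` after diagnosis:
        F(d) - F(d-1) for d within the window, 0 beyond it (cure)."""
        if d < 1:
            raise DomainError(f"year index must be >= 1, got {d}")
        if d > self.window:
            return 0.0
        return float(self.cdf(d) - self.cdf(d - 1))

    def interval_probs(self) -> np.ndarray:
        """Vector of the ``window`` annual progression probabilities."""
        edges = weibull_cdf(np.arange(0, self.window + 1), self.alpha, self.beta)
        return np.diff(edges)


@dataclass(frozen=True)
class MortalityModel:
    """Post-advanced overall survival per histology, anchored on median OS.

    Only the median is published, so the shape defaults to 1 (exponential);
    the scale satisfies S(median) = 0.5 exactly for any shape.
    """

    histology: str
    median_os_months: float
    beta: float = 1.0

    def __post_init__(self):
        if self.median_os_months <= 0:
            raise ValidationError(f"median OS must be > 0, got {self.median_os_months}")
        if self.beta <= 0:
            raise ValidationError(f"shape must be > 0, got {self.beta}")

    @property
    def alpha(self) -> float:
        # F(median) = 0.5  =>  alpha = median / (ln 2)**(1/beta)
        return calibrate_weibull_scale(0.5, self.median_os_months, self.beta)

    def survival_fraction(self, t_months) -> float:
        """Proportion alive at ``t_months`` after entering the advanced pool."""
        t = np.asarray(t_months, dtype=float)
        if np.any(t < 0):
            raise DomainError("time must be >= 0")
        out = np.exp(-np.power(t / self.alpha, self.beta))
        return float(out) if out.ndim == 0 else out


def model_to_dict(model) -> dict:
    """JSON-ready dump of a progression or mortality model."""
    if isinstance(model, ProgressionModel):
        return {"kind": "progression", "stage": model.stage, "alpha": model.alpha,
                "beta": model.beta, "anchor_p5": model.p5, "window": model.window}
    return {"kind": "mortality", "histology": model.histology, "alpha": model.alpha,
            "beta": model.beta, "median_os_months": model.median_os_months}
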