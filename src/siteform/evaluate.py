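"""Correlation and regression evaluation of site form against stand responses.

Two claims are testable once SF values and stand responses are on the
table: (i) SF correlates with volume productivity (PAI), and (ii) SF is
independent of stand density (SDI).  Both are assessed with Pearson's
correlation on the square-root-transformed response (the transform
stabilises the right-skewed increment/density scales; the raw scale remains
available), backed by ordinary least squares with Shapiro-Wilk residual
diagnostics, and stratified over four stand-mixture levels defined by the
proportion of coniferous individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DomainError, ZeroVarianceError
from .schumacher import fit_statistics

SQRT = "sqrt"
NONE = "none"

ALPHA = 0.05  # significance level for coefficient flags


@dataclass
class MixtureStratum:
    """One conifer-proportion interval; strata partition [0, 1]."""

    label: str
    lower: float
    upper: float
    closed_lower: bool = False  # first stratum includes its lower bound

    def contains(self, value: float) -> bool:
        if self.closed_lower:
            return self.lower <= value <= self.upper
        return self.lower < value <= self.upper


def default_mixture_strata() -> list[MixtureStratum]:
    """The four conifer-proportion levels: [0, .25], (.25, .5], (.5, .75], (.75, 1]."""
    return [
        MixtureStratum("0-0.25", 0.0, 0.25, closed_lower=True),
        MixtureStratum("0.25-0.5", 0.25, 0.5),
        MixtureStratum("0.5-0.75", 0.5, 0.75),
        MixtureStratum("0.75-1", 0.75, 1.0),
    ]


@dataclass
class EvaluationResult:
    n: int
    r_pearson: float | None = None
    p_value: float | None = None
    intercept: float | None = None
    slope: float | None = None
    intercept_ns: bool | None = None  # True when not significant at ALPHA
    slope_ns: bool | None = None
    r2_adj: float | None = None
    rmse: float | None = None
    shapiro_w: float | None = None
    shapiro_p: float | None = None
    available: bool = True


def _transform(response: np.ndarray, transform: str) -> np.ndarray:
    if transform == NONE:
        return response
    if transform == SQRT:
        if np.any(response < 0):
            raise DomainError("sqrt transform requires a non-negative response")
        return np.sqrt(response)
    raise ValueError(f"unknown transform {transform!r}")


def correlate_sf_response(
    sf_values, response, transform: str = SQRT
) -> EvaluationResult:
    """Pearson correlation between SF and a (transformed) stand response."""
    x = np.asarray(sf_values, dtype=float)
    y = _transform(np.asarray(response, dtype=float), transform)
    if x.size != y.size:
        raise ValueError("sf and response must be paired")
    if x.size < 3:
        raise DomainError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined: a column is constant")
    r, p = sps.pearsonr(x, y)
    return EvaluationResult(n=int(x.size), r_pearson=float(r), p_value=float(p))


def regress_sf_response(
    sf_values, response, transform: str = SQRT
) -> EvaluationResult:
    """OLS of the (transformed) response on SF, with residual diagnostics."""
    x = np.asarray(sf_values, dtype=float)
    y = _transform(np.asarray(response, dtype=float), transform)
    if x.size != y.size:
        raise ValueError("sf and response must be paired")
    if x.size < 3:
        raise DomainError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("regression undefined: SF is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(model.resid)
    stats = fit_statistics(y, np.asarray(model.fittedvalues), p=2)
    if np.ptp(resid) == 0:
        shapiro_w, shapiro_p = 1.0, 1.0  # exact fit: nothing to test
    else:
        shapiro_w, shapiro_p = sps.shapiro(resid)
    r = correlate_sf_response(x, y, transform=NONE) if np.ptp(y) > 0 else None
    return EvaluationResult(
        n=int(x.size),
        r_pearson=None if r is None else r.r_pearson,
        p_value=None if r is None else r.p_value,
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        intercept_ns=bool(model.pvalues[0] >= ALPHA),
        slope_ns=bool(model.pvalues[1] >= ALPHA),
        r2_adj=stats.r2_adj,
        rmse=stats.rmse,
        shapiro_w=float(shapiro_w),
        shapiro_p=float(shapiro_p),
    )


def stratified_correlations(
    sf_values,
    response,
    conifer_prop,
    transform: str = SQRT,
    strata: list[MixtureStratum] | None = None,
) -> list[tuple[MixtureStratum, EvaluationResult]]:
    """Pearson correlation within each stand-mixture stratum.

    Strata with fewer than 3 plots (or a constant column) yield a result
    marked unavailable rather than an exception.
    """
    x = np.asarray(sf_values, dtype=float)
    y = np.asarray(response, dtype=float)
    cp = np.asarray(conifer_prop, dtype=float)
    if not (x.size == y.size == cp.size):
        raise ValueError("sf, response and conifer_prop must be aligned")
    if np.any((cp < 0) | (cp > 1)):
        raise DomainError("conifer proportions must lie in [0, 1]")
    strata = strata or default_mixture_strata()
    out: list[tuple[MixtureStratum, EvaluationResult]] = []
    for stratum in strata:
        mask = np.array([stratum.contains(v) for v in cp])
        n = int(mask.sum())
        try:
            res = correlate_sf_response(x[mask], y[mask], transform=transform)
        except (DomainError, ZeroVarianceError):
            res = EvaluationResult(n=n, available=False)
        out.append((stratum, res))
    return out
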