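"""Schumacher height-diameter model, its ADA/GADA difference forms, fitting.

The base model expresses total height (m) as a function of dbh (cm),

    h = 1.3 + exp(beta0 + beta1 / dbh),

with beta1 < 0 for an increasing curve that approaches the asymptote
1.3 + exp(beta0).  Re-expressing the model as a projection from an observed
state (H1, D1) to a new diameter D2 gives the algebraic difference approach
(ADA), in which the level parameter cancels and a single shape parameter
beta1 > 0 remains,

    H2 = 1.3 + (H1 - 1.3) * exp(-beta1 / D2) / exp(-beta1 / D1),

and the generalized form (GADA), in which an unobservable site variable X0
is solved from the initial state and both parameters vary with site,

    X0 = (ln(H1 - 1.3) - beta0 / D1) / (1 + beta1 / D1)
    H2 = 1.3 + exp(X0 + (beta0 + beta1 * X0) / D2).

Both projections are self-referencing (H2 = H1 at D2 = D1) and
path-invariant (projecting D1 -> D2 -> D3 equals D1 -> D3).

Fitting is by nonlinear least squares on the fixed (marginal) difference
curve with multi-start initial values, since exponential-in-1/D models have
flat likelihood regions.  A two-stage scheme provides shrunken unit-level
shape parameters where a random-intercept-style refinement is wanted; the
difference form already conditions on each unit's (H1, D1), which absorbs
most site/unit heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import (
    DegreesOfFreedomError,
    DomainError,
    FittingError,
    InsufficientDataError,
    SingularSiteError,
    UnidentifiableError,
)
from .inventory import LIVE, PlotInventory

ADA = "ADA"
GADA = "GADA"

_EXP_CLIP = 50.0  # exponent guard inside optimisation residuals


@dataclass(frozen=True)
class SchumacherParams:
    """Parameters of one Schumacher curve family.

    ``beta0`` is None for ADA fits, where the level parameter cancels.
    In base-equation form beta1 < 0; in ADA form the fitted beta1 > 0
    (the sign is absorbed by the minus inside exp(-beta1/D)).
    """

    beta0: float | None
    beta1: float


@dataclass(frozen=True)
class GrowthPair:
    """A unit (tree or plot) observed at two consecutive inventories."""

    unit_id: str
    d1: float
    d2: float
    h1: float
    h2: float


@dataclass
class FitStatistics:
    """Goodness-of-fit statistics with difference-model degrees of freedom."""

    r2_adj: float
    rmse: float
    n: int
    p: int
    residuals: np.ndarray
    mean_y: float

    def relative_error(self) -> float:
        """RE (%) = RMSE / mean(y) * 100."""
        if self.mean_y == 0:
            raise DomainError("relative error undefined: mean response is zero")
        return self.rmse / self.mean_y * 100.0


@dataclass
class DifferenceModelFit:
    model: str  # ADA or GADA
    unit: str  # "dominant-tree" or "plot-mean"
    criterion: str  # "tallest", "thickest" (or "all")
    params: SchumacherParams
    stats: FitStatistics


def schumacher_height(dbh, params: SchumacherParams):
    """Height (m) from the base model; requires dbh > 0 and beta0."""
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh <= 0):
        raise DomainError("dbh must be positive")
    if params.beta0 is None:
        raise DomainError("base model needs beta0 (ADA fits carry beta1 only)")
    out = 1.3 + np.exp(params.beta0 + params.beta1 / dbh)
    return float(out) if out.ndim == 0 else out


def ada_project(h1, d1, d2, beta1: float):
    """Project height from (H1, D1) to D2 along the ADA curve family."""
    h1 = np.asarray(h1, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(h1 <= 1.3):
        raise DomainError("H1 must exceed breast height 1.3 m")
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise DomainError("diameters must be positive")
    out = 1.3 + (h1 - 1.3) * np.exp(beta1 / d1 - beta1 / d2)
    return float(out) if out.ndim == 0 else out


def gada_site_variable(h1, d1, beta0: float, beta1: float):
    """The GADA site variable X0 solved from the initial state (H1, D1)."""
    h1 = np.asarray(h1, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    if np.any(h1 <= 1.3):
        raise DomainError("H1 must exceed breast height 1.3 m")
    if np.any(d1 <= 0):
        raise DomainError("diameters must be positive")
    denom = 1.0 + beta1 / d1
    if np.any(np.abs(denom) < 1e-12):
        raise SingularSiteError("1 + beta1/D1 = 0: site variable undefined")
    out = (np.log(h1 - 1.3) - beta0 / d1) / denom
    return float(out) if out.ndim == 0 else out


def gada_project(h1, d1, d2, params: SchumacherParams):
    """Project height from (H1, D1) to D2 along the GADA curve family."""
    if params.beta0 is None:
        raise DomainError("GADA projection needs beta0")
    d2 = np.asarray(d2, dtype=float)
    if np.any(d2 <= 0):
        raise DomainError("diameters must be positive")
    x0 = gada_site_variable(h1, d1, params.beta0, params.beta1)
    out = 1.3 + np.exp(np.asarray(x0) + (params.beta0 + params.beta1 * np.asarray(x0)) / d2)
    return float(out) if out.ndim == 0 else out


def fit_statistics(y, yhat, p: int) -> FitStatistics:
    """Adjusted R2, RMSE and residuals with n - p degrees of freedom:

    R2_adj = 1 - [(n-1) SSE] / [(n-p) SST],  RMSE = sqrt(SSE / (n-p)).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    n = y.size
    if n <= p:
        raise DegreesOfFreedomError(f"n={n} <= p={p}")
    resid = y - yhat
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        r2_adj = 1.0 if sse == 0.0 else -np.inf
    else:
        r2_adj = 1.0 - ((n - 1) * sse) / ((n - p) * sst)
    rmse = float(np.sqrt(sse / (n - p)))
    return FitStatistics(
        r2_adj=float(r2_adj), rmse=rmse, n=n, p=p, residuals=resid,
        mean_y=float(y.mean()),
    )


def _pair_arrays(pairs: Sequence[GrowthPair]):
    d1 = np.array([p.d1 for p in pairs], dtype=float)
    d2 = np.array([p.d2 for p in pairs], dtype=float)
    h1 = np.array([p.h1 for p in pairs], dtype=float)
    h2 = np.array([p.h2 for p in pairs], dtype=float)
    if np.any(d2 < d1):
        raise DomainError("growth pairs require D2 >= D1")
    if np.any(h1 <= 1.3) or np.any(h2 <= 1.3):
        raise DomainError("heights in growth pairs must exceed 1.3 m")
    return d1, d2, h1, h2


def _ada_residuals(beta1, h1, d1, d2, h2):
    z = np.clip(beta1 / d1 - beta1 / d2, -_EXP_CLIP, _EXP_CLIP)
    return 1.3 + (h1 - 1.3) * np.exp(z) - h2


def _gada_residuals(theta, h1, d1, d2, h2):
    beta0, beta1 = theta
    denom = 1.0 + beta1 / d1
    if np.any(np.abs(denom) < 1e-9):
        return np.full_like(h2, 1e6)
    x0 = (np.log(h1 - 1.3) - beta0 / d1) / denom
    z = np.clip(x0 + (beta0 + beta1 * x0) / d2, -_EXP_CLIP, _EXP_CLIP)
    return 1.3 + np.exp(z) - h2


# multi-start grids; exponential-in-1/D difference models have flat
# likelihood regions, so single-start optimisation is unreliable
_ADA_STARTS = np.geomspace(1.0, 200.0, 6)
_GADA_B0_STARTS = (-100.0, 100.0, 300.0, 600.0, 1200.0)
_GADA_RATIOS = (-0.05, -0.15, -0.27, -0.40)
# box keeping the optimiser off the flat large-parameter ridge where the
# GADA family degenerates into its ADA limit
_GADA_BOUNDS = ([-3000.0, -1000.0], [3000.0, 1000.0])


def fit_difference_model(
    pairs: Sequence[GrowthPair],
    model: str,
    unit: str = "dominant-tree",
    criterion: str = "all",
) -> DifferenceModelFit:
    """Fit the ADA (beta1) or GADA (beta0, beta1) difference curve by
    multi-start nonlinear least squares on predicted H2."""
    if len(pairs) < 2:
        raise InsufficientDataError("need at least 2 growth pairs")
    d1, d2, h1, h2 = _pair_arrays(pairs)
    if np.allclose(d1, d2):
        raise UnidentifiableError("all pairs have D2 = D1: no growth signal")

    if model == ADA:
        best = None
        for start in _ADA_STARTS:
            try:
                sol = least_squares(
                    _ada_residuals, x0=[start], args=(h1, d1, d2, h2),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, method="lm",
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.isfinite(best.cost):
            raise FittingError("ADA fit did not converge from any start")
        beta1 = float(best.x[0])
        params = SchumacherParams(beta0=None, beta1=beta1)
        yhat = ada_project(h1, d1, d2, beta1)
        stats = fit_statistics(h2, yhat, p=1)
    elif model == GADA:
        best = None
        for b0 in _GADA_B0_STARTS:
            for r in _GADA_RATIOS:
                try:
                    sol = least_squares(
                        _gada_residuals, x0=[b0, r * b0], args=(h1, d1, d2, h2),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, method="trf",
                        bounds=_GADA_BOUNDS,
                    )
                except Exception:
                    continue
                if not np.all(np.isfinite(sol.x)):
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None or not np.isfinite(best.cost):
            raise FittingError("GADA fit did not converge from any start")
        params = SchumacherParams(beta0=float(best.x[0]), beta1=float(best.x[1]))
        yhat = gada_project(h1, d1, d2, params)
        stats = fit_statistics(h2, yhat, p=2)
    else:
        raise ValueError(f"unknown difference model {model!r}")

    return DifferenceModelFit(
        model=model, unit=unit, criterion=criterion, params=params, stats=stats
    )


def _base_model(dbh, beta0, beta1):
    return 1.3 + np.exp(beta0 + beta1 / dbh)


def _base_jac(dbh, beta0, beta1):
    e = np.exp(beta0 + beta1 / dbh)
    return np.column_stack([e, e / dbh])


def fit_plot_height_model(
    plot: PlotInventory | tuple[np.ndarray, np.ndarray],
) -> tuple[SchumacherParams, FitStatistics]:
    """Least-squares fit of the base model to one plot's live trees.

    Accepts a :class:`PlotInventory` (live trees with measured heights above
    breast height are used, all species pooled) or a ``(dbh, h)`` array pair.
    Initialisation linearises ln(h - 1.3) on 1/dbh, then the fit is refined
    on the height scale.
    """
    if isinstance(plot, PlotInventory):
        usable = [
            t for t in plot.trees
            if t.status == LIVE and t.has_height and t.h > 1.3 and t.dbh > 0
        ]
        dbh = np.array([t.dbh for t in usable], dtype=float)
        h = np.array([t.h for t in usable], dtype=float)
    else:
        dbh = np.asarray(plot[0], dtype=float)
        h = np.asarray(plot[1], dtype=float)
        keep = (h > 1.3) & (dbh > 0)
        dbh, h = dbh[keep], h[keep]

    if dbh.size < 4:
        raise InsufficientDataError(
            f"need >= 4 trees with measured height, got {dbh.size}"
        )
    if np.ptp(dbh) < 1e-9:
        raise UnidentifiableError("all trees share one dbh: curve unidentifiable")

    x = 1.0 / dbh
    z = np.log(h - 1.3)
    b1_init, b0_init = np.polyfit(x, z, 1)
    try:
        popt, _ = curve_fit(
            _base_model, dbh, h, p0=[b0_init, b1_init], jac=_base_jac,
            maxfev=200,
        )
    except Exception as exc:  # non-convergence / runtime failure
        raise FittingError(f"plot height model did not converge: {exc}") from exc
    params = SchumacherParams(beta0=float(popt[0]), beta1=float(popt[1]))
    stats = fit_statistics(h, _base_model(dbh, *popt), p=2)
    return params, stats


def two_stage_unit_effects(
    pairs: Iterable[GrowthPair],
    pooled: DifferenceModelFit,
    shrinkage_n0: float = 20.0,
) -> dict[str, float]:
    """Shrunken unit-level ADA shape parameters (two-stage scheme).

    Stage one fits beta1 per unit; stage two shrinks each estimate toward
    the pooled value with weight n_u / (n_u + n0), so sparsely observed
    units borrow strength from the population curve.
    """
    if pooled.model != ADA:
        raise ValueError("unit-level refinement is defined for ADA fits")
    by_unit: dict[str, list[GrowthPair]] = {}
    for p in pairs:
        by_unit.setdefault(p.unit_id, []).append(p)
    out: dict[str, float] = {}
    for unit_id, unit_pairs in by_unit.items():
        d1, d2, h1, h2 = _pair_arrays(unit_pairs)
        n_u = len(unit_pairs)
        if np.allclose(d1, d2):
            out[unit_id] = pooled.params.beta1
            continue
        sol = least_squares(
            _ada_residuals, x0=[pooled.params.beta1], args=(h1, d1, d2, h2),
            xtol=1e-10, ftol=1e-10, method="lm",
        )
        w = n_u / (n_u + shrinkage_n0)
        out[unit_id] = float(w * sol.x[0] + (1 - w) * pooled.params.beta1)
    return out


def tree_growth_pairs(series, dset) -> list[GrowthPair]:
    """Consecutive-inventory (D, H) pairs for each dominant tree."""
    pairs: list[GrowthPair] = []
    idxs = [inv.inventory_index for inv in series.inventories]
    for tid in dset.tree_ids:
        obs = series.observations(tid)
        for a, b in zip(idxs[:-1], idxs[1:]):
            o1, o2 = obs.get(a), obs.get(b)
            if o1 is None or o2 is None:
                continue
            if not (o1.has_height and o2.has_height):
                continue
            pairs.append(
                GrowthPair(
                    unit_id=f"{series.plot_id}/{tid}",
                    d1=o1.dbh, d2=max(o2.dbh, o1.dbh), h1=o1.h, h2=o2.h,
                )
            )
    return pairs


def plot_mean_growth_pairs(summary) -> list[GrowthPair]:
    """Consecutive-inventory (MD, MH) pairs for one plot's dominant set."""
    pairs: list[GrowthPair] = []
    for i in range(len(summary.md) - 1):
        pairs.append(
            GrowthPair(
                unit_id=summary.plot_id,
                d1=float(summary.md[i]),
                d2=float(max(summary.md[i + 1], summary.md[i])),
                h1=float(summary.mh[i]),
                h2=float(summary.mh[i + 1]),
            )
        )
    return pairs
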