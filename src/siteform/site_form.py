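"""Site-form (SF) estimators, reference-diameter selection, SF-class curves.

Site form replaces the age axis of the classical site index with diameter:
it is the expected (mean) dominant height at a reference diameter, so it
remains defined in uneven-aged multispecies stands where ages are unknown
or meaningless.  Three estimators are provided:

* ``SF_H-D``   — each dominant tree's (H, D) is projected individually to
  the reference diameter along an ADA or GADA curve family and the
  projected heights are averaged;
* ``SF_MH-MD`` — the plot-mean dominant state (MH, MD) is projected once;
* ``SF_h-dbh`` — the plot-specific base height-diameter curve, fitted on
  all live trees of the plot, is evaluated at the reference diameter.

Projecting individually and averaging differs from projecting the mean
(the projection is nonlinear in H and D); the two agree only when all
dominants are identical.  With two dominant definitions (tallest/thickest)
and two difference models (ADA/GADA), a complete plot-period yields
4 + 4 + 1 = 9 SF values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dominants import DominantSet, DominantSummary
from .errors import DomainError, InsufficientDataError
from .inventory import PlotSeries
from .schumacher import (
    ADA,
    GADA,
    DifferenceModelFit,
    FitStatistics,
    SchumacherParams,
    ada_project,
    fit_plot_height_model,
    fit_statistics,
    gada_project,
    schumacher_height,
)

METHOD_HD = "SF_H-D"
METHOD_MHMD = "SF_MH-MD"
METHOD_HDBH = "SF_h-dbh"

#: Default reference diameter (cm) at which site form is read off.
DEFAULT_REFERENCE_DIAMETER = 40.0

#: Candidate reference-diameter grid (cm) and class width for RE profiling.
DEFAULT_REFERENCE_GRID = tuple(float(d) for d in range(10, 65, 5))
DEFAULT_CLASS_WIDTH = 5.0

#: A grid diameter is on the low-RE plateau when its RE is within 5% of the
#: minimum; the smallest such diameter is selected.
PLATEAU_TOLERANCE = 0.05


@dataclass(frozen=True)
class SiteFormEstimate:
    plot_id: str
    inventory_index: int
    method: str  # METHOD_HD, METHOD_MHMD or METHOD_HDBH
    model: str  # ADA, GADA or "plot-h-dbh"
    criterion: str  # "tallest", "thickest" or "all"
    reference_diameter: float
    value: float  # m


def _project(h1, d1, d_ref: float, fit: DifferenceModelFit):
    if fit.model == ADA:
        return ada_project(h1, d1, d_ref, fit.params.beta1)
    if fit.model == GADA:
        return gada_project(h1, d1, d_ref, fit.params)
    raise ValueError(f"unknown model {fit.model!r}")


def site_form_hd(
    series: PlotSeries,
    inventory_index: int,
    dset: DominantSet,
    fit: DifferenceModelFit,
    d_ref: float = DEFAULT_REFERENCE_DIAMETER,
) -> SiteFormEstimate:
    """SF_H-D: mean of the dominants' individually projected heights."""
    if fit.unit != "dominant-tree":
        raise ValueError("SF_H-D requires a dominant-tree (H-D) model fit")
    values = []
    for tid in dset.tree_ids:
        obs = series.observations(tid).get(inventory_index)
        if obs is None or not obs.has_height:
            raise DomainError(
                f"plot {series.plot_id}, tree {tid}: no (D, H) observation at "
                f"inventory {inventory_index}"
            )
        try:
            values.append(_project(obs.h, obs.dbh, d_ref, fit))
        except DomainError as exc:
            raise DomainError(f"tree {tid}: {exc}") from exc
    return SiteFormEstimate(
        plot_id=series.plot_id,
        inventory_index=inventory_index,
        method=METHOD_HD,
        model=fit.model,
        criterion=dset.criterion,
        reference_diameter=d_ref,
        value=float(np.mean(values)),
    )


def site_form_mhmd(
    summary: DominantSummary,
    inventory_index: int,
    fit: DifferenceModelFit,
    d_ref: float = DEFAULT_REFERENCE_DIAMETER,
) -> SiteFormEstimate:
    """SF_MH-MD: projection of the plot-mean dominant state (MH, MD)."""
    if fit.unit != "plot-mean":
        raise ValueError("SF_MH-MD requires a plot-mean (MH-MD) model fit")
    md = float(summary.md[inventory_index])
    mh = float(summary.mh[inventory_index])
    if md <= 0 or mh <= 1.3:
        raise DomainError(
            f"plot {summary.plot_id}: invalid mean state MD={md}, MH={mh}"
        )
    return SiteFormEstimate(
        plot_id=summary.plot_id,
        inventory_index=inventory_index,
        method=METHOD_MHMD,
        model=fit.model,
        criterion=summary.criterion,
        reference_diameter=d_ref,
        value=float(_project(mh, md, d_ref, fit)),
    )


def site_form_hdbh(
    plot_id: str,
    inventory_index: int,
    params: SchumacherParams,
    d_ref: float = DEFAULT_REFERENCE_DIAMETER,
) -> SiteFormEstimate:
    """SF_h-dbh: the plot-specific base curve evaluated at d_ref."""
    return SiteFormEstimate(
        plot_id=plot_id,
        inventory_index=inventory_index,
        method=METHOD_HDBH,
        model="plot-h-dbh",
        criterion="all",
        reference_diameter=d_ref,
        value=float(schumacher_height(d_ref, params)),
    )


@dataclass
class ReferenceDiameterProfile:
    """Relative prediction error per candidate reference diameter."""

    grid: np.ndarray  # cm
    re: np.ndarray  # percent; NaN where the class was empty/undersized
    n_per_class: np.ndarray
    selected: float  # cm
    warnings: list[str] = field(default_factory=list)


def reference_diameter_profile(
    diameters,
    observed,
    predicted,
    grid=DEFAULT_REFERENCE_GRID,
    class_width: float = DEFAULT_CLASS_WIDTH,
    p: int = 1,
    plateau_tolerance: float = PLATEAU_TOLERANCE,
) -> ReferenceDiameterProfile:
    """Profile the relative error (RE, %) across diameter classes and select
    the reference diameter.

    Observations are binned into classes of width ``class_width`` centred on
    the grid points; RE per class is RMSE (with ``p`` model parameters) as a
    percentage of the class mean observed response.  The selected diameter
    is the smallest grid point whose RE lies on the low-RE plateau, i.e.
    within ``plateau_tolerance`` (relative) of the minimum RE.
    """
    d = np.asarray(diameters, dtype=float)
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if d.size == 0:
        raise DomainError("no observations to profile")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DomainError("empty reference-diameter grid")

    re = np.full(grid.shape, np.nan)
    n_per_class = np.zeros(grid.shape, dtype=int)
    warn: list[str] = []
    for i, g in enumerate(grid):
        mask = np.abs(d - g) <= class_width / 2.0
        n_per_class[i] = int(mask.sum())
        if n_per_class[i] <= p:
            warn.append(
                f"class {g:g} cm: {n_per_class[i]} observation(s), RE undefined"
            )
            continue
        stats = fit_statistics(y[mask], yhat[mask], p=p)
        re[i] = stats.relative_error()

    valid = np.isfinite(re)
    if not valid.any():
        raise DomainError("RE undefined on every diameter class")
    min_re = float(np.nanmin(re))
    threshold = min_re * (1.0 + plateau_tolerance)
    on_plateau = valid & (re <= threshold)
    selected = float(grid[on_plateau][0])
    return ReferenceDiameterProfile(
        grid=grid, re=re, n_per_class=n_per_class, selected=selected,
        warnings=warn,
    )


@dataclass
class SFClassCurve:
    lower: float
    upper: float
    params: SchumacherParams
    stats: FitStatistics
    n_plots: int
    n_trees: int


def sf_class_curves(
    sf_by_plot: dict[str, float],
    trees_by_plot: dict[str, tuple[np.ndarray, np.ndarray]],
    n_classes: int,
) -> list[SFClassCurve]:
    """Base curves per SF_h-dbh class.

    Plots are partitioned into ``n_classes`` equal-width SF intervals and
    one base model is fitted to the pooled live trees of each class.  When
    all plots share one SF value the partition is degenerate and every class
    is fitted on the pooled union.
    """
    if len(sf_by_plot) < n_classes:
        raise InsufficientDataError(
            f"{len(sf_by_plot)} plots < {n_classes} classes"
        )
    values = np.array(list(sf_by_plot.values()), dtype=float)
    lo, hi = float(values.min()), float(values.max())
    edges = np.linspace(lo, hi, n_classes + 1)
    degenerate = hi - lo < 1e-12

    curves: list[SFClassCurve] = []
    for k in range(n_classes):
        if degenerate:
            members = list(sf_by_plot)
        else:
            lo_k, hi_k = edges[k], edges[k + 1]
            members = [
                pid
                for pid, v in sf_by_plot.items()
                if (v >= lo_k and (v < hi_k or (k == n_classes - 1 and v <= hi_k)))
            ]
        dbh = np.concatenate(
            [np.asarray(trees_by_plot[pid][0], dtype=float) for pid in members]
        ) if members else np.empty(0)
        h = np.concatenate(
            [np.asarray(trees_by_plot[pid][1], dtype=float) for pid in members]
        ) if members else np.empty(0)
        if dbh.size < 4:
            raise InsufficientDataError(
                f"SF class {k}: {dbh.size} tree(s) < 4, cannot fit curve"
            )
        params, stats = fit_plot_height_model((dbh, h))
        curves.append(
            SFClassCurve(
                lower=float(edges[k]),
                upper=float(edges[k + 1]),
                params=params,
                stats=stats,
                n_plots=len(members),
                n_trees=int(dbh.size),
            )
        )
    return curves
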