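"""Dominant-tree selection and summaries.

Dominance is defined per hectare, regardless of species, as either the 100
tallest or the 100 thickest trees.  On a 2500 m2 plot the quota is therefore
25 trees.  Only trees that were alive and measured (dbh and height) at every
inventory of the series are eligible, so the dominant set is fixed over the
whole study period; trees are ranked by the criterion variable at the first
inventory, with ties broken by the other size variable and then by tree id,
which makes the selection stable under input reordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingHeightError, NoDominantsError
from .inventory import LIVE, PlotSeries

TALLEST = "tallest"
THICKEST = "thickest"


@dataclass
class DominantSet:
    plot_id: str
    criterion: str  # TALLEST or THICKEST
    tree_ids: list[str]  # ordered by rank, best first
    quota: int
    shortfall: bool  # fewer eligible trees than the quota


@dataclass
class DominantSummary:
    """Per-inventory dominant diameters/heights and their plot means.

    ``d`` and ``h`` are (n_inventories, n_trees) arrays aligned with
    ``tree_ids``; ``md`` and ``mh`` are the per-inventory arithmetic means
    (the MD and MH series used by the plot-mean difference models).
    """

    plot_id: str
    criterion: str
    tree_ids: list[str]
    d: np.ndarray  # cm
    h: np.ndarray  # m
    md: np.ndarray  # cm, per inventory
    mh: np.ndarray  # m, per inventory


def select_dominants(
    series: PlotSeries, criterion: str, per_ha: float = 100.0
) -> DominantSet:
    """Select the dominant trees of a plot under one criterion.

    Raises :class:`NoDominantsError` when no tree is alive and fully
    measured at every inventory.
    """
    if criterion not in (TALLEST, THICKEST):
        raise ValueError(f"unknown criterion {criterion!r}")
    if series.n_inventories < 2:
        raise NoDominantsError(
            f"plot {series.plot_id}: need >= 2 inventories to define "
            "re-measured dominants"
        )
    if per_ha <= 0:
        raise ValueError("per_ha must be positive")
    quota = int(round(per_ha * series.area_m2 / 10000.0))

    all_idx = [inv.inventory_index for inv in series.inventories]
    candidates: list[tuple[str, float, float]] = []  # (tree_id, h0, dbh0)
    for tid in series.tree_ids():
        obs = series.observations(tid)
        if not all(i in obs for i in all_idx):
            continue
        if not all(obs[i].status == LIVE and obs[i].has_height for i in all_idx):
            continue
        first = obs[min(all_idx)]
        candidates.append((tid, float(first.h), float(first.dbh)))
    if not candidates:
        raise NoDominantsError(
            f"plot {series.plot_id}: no re-measured live trees with complete "
            "measurements"
        )

    if criterion == TALLEST:
        key = lambda c: (-c[1], -c[2], c[0])
    else:
        key = lambda c: (-c[2], -c[1], c[0])
    ranked = sorted(candidates, key=key)
    chosen = ranked[:quota]
    return DominantSet(
        plot_id=series.plot_id,
        criterion=criterion,
        tree_ids=[c[0] for c in chosen],
        quota=quota,
        shortfall=len(candidates) < quota,
    )


def dominant_summary(dset: DominantSet, series: PlotSeries) -> DominantSummary:
    """Per-inventory (D, H) pairs and their means for a dominant set."""
    idxs = [inv.inventory_index for inv in series.inventories]
    n_inv, n_tree = len(idxs), len(dset.tree_ids)
    d = np.empty((n_inv, n_tree))
    h = np.empty((n_inv, n_tree))
    missing: list[str] = []
    for j, tid in enumerate(dset.tree_ids):
        obs = series.observations(tid)
        for i, inv_idx in enumerate(idxs):
            o = obs.get(inv_idx)
            if o is None or not o.has_height:
                missing.append(tid)
                break
            d[i, j] = o.dbh
            h[i, j] = o.h
    if missing:
        raise MissingHeightError(
            f"plot {series.plot_id}: dominant trees missing height or "
            f"observation: {sorted(set(missing))}"
        )
    return DominantSummary(
        plot_id=series.plot_id,
        criterion=dset.criterion,
        tree_ids=list(dset.tree_ids),
        d=d,
        h=h,
        md=d.mean(axis=1),
        mh=h.mean(axis=1),
    )
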