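"""Per-plot stand attributes: volume, increment, density and composition.

All per-hectare quantities use the expansion factor 10000 / area_m2.
Tree volume is the combined stem-plus-branch equation
v = a0 * dbh^a1 * h^a2 + a3 * dbh^2 (m3; dbh cm, h m) with species-specific
coefficients and a group-level fallback.  The periodic annual increment
(PAI, m3 ha-1 yr-1) sums per-tree volume differences of trees alive at both
inventories of a period, divided by the period length — trees that died
during the period and ingrowth crossing the callipering threshold do not
enter the sum.  Density is Reineke's stand density index
SDI = N * (Dq / 25.4)^1.605.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoefficientError, DomainError
from .inventory import (
    CONIFER,
    CoefficientTable,
    PlotInventory,
    PlotSeries,
    VolumeCoefficients,
)

REINEKE_REFERENCE_DQ = 25.4  # cm
REINEKE_EXPONENT = 1.605


@dataclass
class StandMetrics:
    plot_id: str
    inventory_index: int
    s: int  # species richness
    n: float  # trees per hectare
    g: float  # basal area, m2 ha-1
    v: float  # stand volume, m3 ha-1
    dq: float  # quadratic mean diameter, cm
    sdi: float  # Reineke index
    conifer_prop: float  # fraction of live individuals that are conifers


def tree_volume(dbh, h, coef: VolumeCoefficients):
    """Total tree volume (m3) from dbh (cm) and height (m)."""
    dbh = np.asarray(dbh, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(dbh <= 0) or np.any(h <= 0):
        raise DomainError("dbh and h must be positive")
    v = coef.a0 * dbh**coef.a1 * h**coef.a2 + coef.a3 * dbh**2
    if np.any(np.asarray(v) < 0):
        raise CoefficientError(
            f"coefficient set {coef.key!r} produced a negative volume"
        )
    return float(v) if v.ndim == 0 else v


def compute_sdi(n: float, dq: float) -> float:
    """Reineke's stand density index from trees/ha and Dq (cm)."""
    if n < 0:
        raise DomainError("N must be non-negative")
    if n == 0:
        return 0.0
    if dq <= 0:
        raise DomainError("Dq must be positive when N > 0")
    return float(n * (dq / REINEKE_REFERENCE_DQ) ** REINEKE_EXPONENT)


def compute_pai(
    series: PlotSeries,
    inventory_pair: tuple[int, int],
    coefs: CoefficientTable,
) -> float:
    """Periodic annual increment (m3 ha-1 yr-1) over one inventory pair.

    Survivor-only: a tree contributes (V2 - V1) / period_years, extrapolated
    to one hectare, when it is live with measured dbh and h at both
    inventories of the pair.
    """
    if series.period_years <= 0:
        raise DomainError("period_years must be positive")
    i1, i2 = inventory_pair
    by_index = {inv.inventory_index: inv for inv in series.inventories}
    if i1 not in by_index or i2 not in by_index:
        raise DomainError(f"inventory pair {inventory_pair} not present")
    factor = 10000.0 / series.area_m2
    total = 0.0
    inv1, inv2 = by_index[i1], by_index[i2]
    obs2 = {t.tree_id: t for t in inv2.trees}
    for t1 in inv1.trees:
        t2 = obs2.get(t1.tree_id)
        if t2 is None:
            continue
        if t1.status != "live" or t2.status != "live":
            continue
        if not (t1.has_height and t2.has_height):
            continue
        c1 = coefs.lookup(t1.species_code, t1.species_group)
        c2 = coefs.lookup(t2.species_code, t2.species_group)
        dv = tree_volume(t2.dbh, t2.h, c2) - tree_volume(t1.dbh, t1.h, c1)
        total += dv / series.period_years * factor
    return total


def stand_summary(plot: PlotInventory, coefs: CoefficientTable) -> StandMetrics:
    """Whole-stand attributes of one plot inventory (live trees only).

    Trees without a height measurement are excluded from the volume sum but
    contribute to N, G, Dq and composition.
    """
    live = plot.live_trees()
    if not live:
        raise DomainError(f"plot {plot.plot_id}: no live trees")
    factor = plot.expansion_factor
    dbh = np.array([t.dbh for t in live], dtype=float)
    n = len(live) * factor
    g = float(np.sum(np.pi * (dbh / 200.0) ** 2)) * factor
    dq = float(np.sqrt(np.mean(dbh**2)))
    v = 0.0
    for t in live:
        if t.has_height:
            v += tree_volume(t.dbh, t.h, coefs.lookup(t.species_code, t.species_group))
    v *= factor
    species = {t.species_code for t in live}
    conifer_prop = sum(1 for t in live if t.species_group == CONIFER) / len(live)
    return StandMetrics(
        plot_id=plot.plot_id,
        inventory_index=plot.inventory_index,
        s=len(species),
        n=float(n),
        g=g,
        v=float(v),
        dq=dq,
        sdi=compute_sdi(float(n), dq),
        conifer_prop=float(conifer_prop),
    )


def importance_value_index(inventories: list[PlotInventory]) -> pd.DataFrame:
    """Per-species importance value index over a set of plot inventories.

    IVI = relative abundance + relative basal area + relative frequency,
    each component expressed as a fraction of its column total (relative
    frequency normalises plot-of-occurrence counts over species), so the
    IVI column sums to 3.
    """
    if not inventories:
        raise DomainError("no inventories supplied")
    counts: dict[str, int] = {}
    basal: dict[str, float] = {}
    occupancy: dict[str, set[str]] = {}
    for inv in inventories:
        for t in inv.live_trees():
            counts[t.species_code] = counts.get(t.species_code, 0) + 1
            basal[t.species_code] = (
                basal.get(t.species_code, 0.0) + np.pi * (t.dbh / 200.0) ** 2
            )
            occupancy.setdefault(t.species_code, set()).add(inv.plot_id)
    species = sorted(counts)
    n_tot = sum(counts.values())
    g_tot = sum(basal.values())
    f_tot = sum(len(occupancy[s]) for s in species)
    df = pd.DataFrame(
        {
            "species_code": species,
            "rel_abundance": [counts[s] / n_tot for s in species],
            "rel_basal_area": [basal[s] / g_tot for s in species],
            "rel_frequency": [len(occupancy[s]) / f_tot for s in species],
        }
    )
    df["ivi"] = df.rel_abundance + df.rel_basal_area + df.rel_frequency
    return df.set_index("species_code")
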