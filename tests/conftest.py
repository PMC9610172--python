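import numpy as np
import pytest

from siteform.inventory import (
    CoefficientTable,
    PlotInventory,
    PlotSeries,
    TreeObservation,
    VolumeCoefficients,
)
from siteform.simulate import SyntheticConfig, default_volume_table, generate_forest


def make_tree(tree_id, dbh, h, *, species="PIDU", group="conifer",
              status="live", inv=0, year=2007):
    return TreeObservation(
        tree_id=tree_id, species_code=species, species_group=group,
        dbh=dbh, h=h, status=status, inventory_index=inv, year=year,
    )


def make_series(plot_id, rows, area_m2=2500.0, period_years=5.0):
    """Build a PlotSeries from (tree_id, inv, dbh, h[, kwargs]) tuples."""
    by_inv = {}
    for row in rows:
        tid, inv, dbh, h = row[:4]
        kw = row[4] if len(row) > 4 else {}
        year = 2007 + int(inv * period_years)
        by_inv.setdefault(inv, []).append(
            make_tree(tid, dbh, h, inv=inv, year=year, **kw)
        )
    inventories = [
        PlotInventory(plot_id=plot_id, area_m2=area_m2, inventory_index=i,
                      year=2007 + int(i * period_years), trees=trees)
        for i, trees in sorted(by_inv.items())
    ]
    return PlotSeries(plot_id, inventories, period_years=period_years)


@pytest.fixture(scope="session")
def small_forest():
    """A 12-plot synthetic network kept small enough for repeated pipeline runs."""
    cfg = SyntheticConfig(n_plots=12, trees_per_plot_mean=45.0, seed=2024)
    series, truths = generate_forest(cfg)
    return series, truths


@pytest.fixture(scope="session")
def volume_table():
    return default_volume_table()


@pytest.fixture()
def simple_coefs():
    """Diameter-squared-times-height volume: easy to verify by hand."""
    return CoefficientTable(
        [VolumeCoefficients("default", 8e-5, 2.0, 1.0, 0.0)]
    )


@pytest.fixture()
def noiseless_plot_curve():
    """A plot whose heights sit exactly on a known Schumacher curve."""
    rng = np.random.default_rng(5)
    dbh = rng.uniform(8, 60, size=30)
    h = 1.3 + np.exp(3.4 - 20.0 / dbh)
    return dbh, h
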