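"""Synthetic multi-inventory uneven-aged multispecies stand generator.

The generator emulates the structure of a permanent-plot network in
temperate pine-oak forest: square 2500 m2 plots re-measured at 5-year
intervals, every tree with dbh >= 7.5 cm callipered, a right-skewed
diameter distribution, conifer proportions spanning [0, 1], and a
plot-level site effect that raises the whole height-diameter curve.

Ground truth is known by construction: each plot's heights follow the base
Schumacher curve with a plot-specific level offset (the site effect) and a
persistent per-tree level deviation (a tree that is tall for its diameter
stays tall), plus small independent hypsometer measurement noise at every
inventory; diameter growth is a Gamma increment whose mean increases with
the site effect, so volume increment (PAI) is positively coupled to site
quality.  Each tree therefore moves along its own height-diameter curve,
which makes the ADA/GADA difference-model assumptions hold by construction
and reproduces the empirical pattern that dominant-tree difference models
fit far more tightly than whole-plot height-diameter curves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, JoinError
from .inventory import (
    BROADLEAF,
    CONIFER,
    LIVE,
    DEAD,
    CoefficientTable,
    PlotInventory,
    PlotSeries,
    TreeObservation,
    VolumeCoefficients,
)

CONIFER_SPECIES = ("PIDU", "PICO", "PIAR", "PITE", "PSME", "JUDE")
BROADLEAF_SPECIES = ("QUSI", "QUDU", "QURU", "ARXA", "ALAC", "FRUH")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic inventory network.

    Defaults emulate the structure of a 2500 m2 permanent-plot network in
    uneven-aged pine-oak forest: ~600 stems/ha above the 7.5 cm callipering
    threshold, a right-skewed (Weibull, shape < 2) dbh distribution, a
    population height curve h = 1.3 + exp(3.3 - 21/dbh) shifted per plot by
    a Normal(0, 0.25) site effect and per tree by a persistent
    Normal(0, 0.33) level deviation (both on the log scale of h - 1.3),
    0.6 m hypsometer measurement noise per inventory, and ~2 cm of diameter
    growth per 5-year period scaled by exp(site effect).  The persistent
    tree effect dominates the residual of whole-plot curve fits (~2.5-3 m,
    the plot-model regime) while difference-model fits that condition on
    each tree's own starting state see only the measurement noise.
    """

    n_plots: int = 100
    area_m2: float = 2500.0
    n_inventories: int = 2
    period_years: float = 5.0
    trees_per_plot_mean: float = 150.0  # ~600/ha on 2500 m2
    # left-truncated Weibull dbh (cm): shape < 2 gives the right skew
    dbh_weibull_shape: float = 1.3
    dbh_weibull_scale: float = 13.0
    dbh_min: float = 7.5
    # population height curve (base-equation scale) and site effect
    beta0: float = 3.3
    beta1: float = -21.0
    site_effect_sd: float = 0.25
    tree_height_effect_sd: float = 0.33  # persistent per-tree, log scale
    height_noise_sd: float = 0.6  # m, fresh measurement draw per inventory
    # diameter growth per period: Gamma(shape, mean * exp(pai_coupling * s))
    dbh_increment_mean: float = 2.0  # cm per period at an average site
    dbh_increment_shape: float = 2.0
    pai_coupling: float = 1.0
    # plot conifer proportion ~ Beta(alpha, beta); (1, 1) spans [0, 1] evenly
    conifer_prop_alpha: float = 1.0
    conifer_prop_beta: float = 1.0
    species_per_plot: tuple[int, int] = (3, 10)
    mortality_rate: float = 0.0  # per-tree per-period death probability
    # fixed systematic design: every plot gets exactly trees_per_plot_mean
    # trees at the truncated-Weibull quantile diameters (no random draws)
    fixed_design: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if self.n_inventories < 2:
            raise ConfigError("need at least 2 inventories")
        for name in (
            "site_effect_sd", "tree_height_effect_sd", "height_noise_sd",
            "mortality_rate", "trees_per_plot_mean", "dbh_increment_mean",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        # feasibility of the truncated dbh distribution
        tail = np.exp(-((self.dbh_min / self.dbh_weibull_scale) ** self.dbh_weibull_shape))
        if tail < 1e-6:
            raise ConfigError(
                "dbh distribution has almost no mass above the callipering "
                "threshold"
            )


@dataclass
class TruthRecord:
    """Per-plot generating truth for estimator validation."""

    plot_id: str
    site_effect: float
    beta0: float  # beta0 + site effect, the plot's true curve level
    beta1: float
    conifer_prop: float  # realized fraction of conifer individuals
    n_trees: int


def default_volume_table() -> CoefficientTable:
    """Group-level stem-plus-branch volume coefficient sets."""
    return CoefficientTable(
        [
            VolumeCoefficients("conifer", 5.5e-5, 2.0, 1.0, 0.0),
            VolumeCoefficients("broadleaf", 6.5e-5, 1.95, 0.95, 1.0e-5),
            VolumeCoefficients("default", 6.0e-5, 2.0, 1.0, 0.0),
        ]
    )


def diameter_only_volume_table() -> CoefficientTable:
    """Height-free volume coefficients (a2 = 0) for null calibration.

    With volume keyed to diameter alone, the response (PAI) shares no
    randomness with the height-based SF estimators, so a configuration with
    zero site effect yields exactly independent SF and PAI.
    """
    return CoefficientTable(
        [
            VolumeCoefficients("conifer", 6.0e-4, 2.0, 0.0, 0.0),
            VolumeCoefficients("broadleaf", 6.5e-4, 2.0, 0.0, 0.0),
            VolumeCoefficients("default", 6.0e-4, 2.0, 0.0, 0.0),
        ]
    )


def decoupled_null_config(seed: int | None = None, **overrides) -> SyntheticConfig:
    """A configuration under which SF carries no site signal.

    Three ingredients make the null exact rather than approximate.  The
    site-effect spread and the growth-site coupling are zero, so SF
    estimates vary only through height noise.  Volume is keyed to diameter
    alone (pair with :func:`diameter_only_volume_table`), so the response
    shares no randomness with the height-based SF estimator.  And the
    diameter design is fixed and systematic (identical quantile diameters
    on every plot), so the SF estimator's design-dependent finite-sample
    bias is the same constant everywhere — with random designs, SF and PAI
    would share the diameter draws and retain a small real correlation.
    Sized small (40 plots of 60 trees) because its use is replicated
    calibration of test size, not single-dataset analysis.
    """
    base = dict(
        n_plots=40,
        trees_per_plot_mean=60.0,
        site_effect_sd=0.0,
        pai_coupling=0.0,
        fixed_design=True,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def _truncated_weibull_icdf(
    u: np.ndarray, shape: float, scale: float, lower: float
) -> np.ndarray:
    """Inverse CDF of a Weibull left-truncated at ``lower``."""
    f_lower = 1.0 - np.exp(-((lower / scale) ** shape))
    u = f_lower + u * (1.0 - f_lower)
    return scale * (-np.log1p(-u)) ** (1.0 / shape)


def _sample_truncated_weibull(
    rng: np.random.Generator, shape: float, scale: float, lower: float, size: int
) -> np.ndarray:
    """Inverse-CDF sampling of a Weibull left-truncated at ``lower``."""
    return _truncated_weibull_icdf(rng.uniform(size=size), shape, scale, lower)


def _assign_species(
    rng: np.random.Generator, n: int, p_conifer: float, n_species: int
) -> tuple[list[str], list[str]]:
    """Species codes and groups for n trees hitting the drawn conifer share."""
    groups = np.where(rng.uniform(size=n) < p_conifer, CONIFER, BROADLEAF)
    n_con_sp = int(round(n_species * p_conifer))
    n_con_sp = min(max(n_con_sp, 1 if (groups == CONIFER).any() else 0),
                   len(CONIFER_SPECIES))
    n_bl_sp = min(max(n_species - n_con_sp, 1 if (groups == BROADLEAF).any() else 0),
                  len(BROADLEAF_SPECIES))
    con_pool = list(rng.choice(CONIFER_SPECIES, size=max(n_con_sp, 1), replace=False))
    bl_pool = list(rng.choice(BROADLEAF_SPECIES, size=max(n_bl_sp, 1), replace=False))
    codes = [
        str(rng.choice(con_pool)) if g == CONIFER else str(rng.choice(bl_pool))
        for g in groups
    ]
    return codes, [str(g) for g in groups]


def generate_forest(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[list[PlotSeries], list[TruthRecord]]:
    """Generate a plot network with known ground truth.

    ``seed`` overrides ``config.seed``; a fixed seed gives bit-identical
    output.  Returns the plot series and one :class:`TruthRecord` per plot.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    first_year = 2007
    years = [first_year + int(i * config.period_years) for i in range(config.n_inventories)]

    series: list[PlotSeries] = []
    truths: list[TruthRecord] = []
    n_digits = max(3, len(str(config.n_plots)))
    for p in range(config.n_plots):
        plot_id = f"P{p:0{n_digits}d}"
        s = rng.normal(0.0, config.site_effect_sd) if config.site_effect_sd > 0 else 0.0
        b0_plot = config.beta0 + s
        if config.fixed_design:
            n_trees = max(4, int(round(config.trees_per_plot_mean)))
        else:
            n_trees = max(4, int(rng.poisson(config.trees_per_plot_mean)))
        p_conifer = float(rng.beta(config.conifer_prop_alpha, config.conifer_prop_beta))
        n_species = int(rng.integers(config.species_per_plot[0],
                                     config.species_per_plot[1] + 1))
        codes, groups = _assign_species(rng, n_trees, p_conifer, n_species)

        if config.fixed_design:
            u = (np.arange(n_trees) + 0.5) / n_trees
            dbh = _truncated_weibull_icdf(
                u, config.dbh_weibull_shape, config.dbh_weibull_scale,
                config.dbh_min,
            )
        else:
            dbh = _sample_truncated_weibull(
                rng, config.dbh_weibull_shape, config.dbh_weibull_scale,
                config.dbh_min, n_trees,
            )
        tree_effect = (
            rng.normal(0.0, config.tree_height_effect_sd, size=n_trees)
            if config.tree_height_effect_sd > 0
            else np.zeros(n_trees)
        )
        alive = np.ones(n_trees, dtype=bool)
        growth_scale = np.exp(config.pai_coupling * s)

        inventories: list[PlotInventory] = []
        for i, year in enumerate(years):
            if i > 0:
                mean_incr = config.dbh_increment_mean * growth_scale
                incr = rng.gamma(
                    config.dbh_increment_shape,
                    mean_incr / config.dbh_increment_shape,
                    size=n_trees,
                )
                dbh = dbh + np.where(alive, incr, 0.0)
                if config.mortality_rate > 0:
                    dies = rng.uniform(size=n_trees) < config.mortality_rate
                    alive &= ~dies
            noise = rng.normal(0.0, config.height_noise_sd, size=n_trees)
            h = 1.3 + np.exp(b0_plot + tree_effect + config.beta1 / dbh) + noise
            h = np.maximum(h, 1.35)  # measured live heights stay above 1.3 m
            trees = [
                TreeObservation(
                    tree_id=f"T{j:04d}",
                    species_code=codes[j],
                    species_group=groups[j],
                    dbh=float(dbh[j]),
                    h=float(h[j]) if alive[j] else None,
                    status=LIVE if alive[j] else DEAD,
                    inventory_index=i,
                    year=year,
                )
                for j in range(n_trees)
            ]
            inventories.append(
                PlotInventory(
                    plot_id=plot_id,
                    area_m2=config.area_m2,
                    inventory_index=i,
                    year=year,
                    trees=trees,
                )
            )
        series.append(PlotSeries(plot_id, inventories, config.period_years))
        truths.append(
            TruthRecord(
                plot_id=plot_id,
                site_effect=float(s),
                beta0=float(b0_plot),
                beta1=float(config.beta1),
                conifer_prop=float(np.mean([g == CONIFER for g in groups])),
                n_trees=n_trees,
            )
        )
    return series, truths


def simulate_growth_pairs(
    model: str,
    params,
    n_pairs: int,
    noise_sd: float,
    rng: np.random.Generator,
    d1_range: tuple[float, float] = (12.0, 55.0),
    increment_range: tuple[float, float] = (1.5, 8.0),
):
    """Remeasurement pairs drawn exactly from an ADA or GADA curve family.

    ``d1`` is uniform over ``d1_range`` (the span of quadratic mean
    diameters reported for diverse pine-oak plot networks, ~12-55 cm, which
    dominant trees straddle) with a uniform 5-year diameter increment; the
    initial height sits on a random curve of the family (ADA: a spread of
    levels; GADA: a spread of the site variable X0), and Gaussian noise of
    ``noise_sd`` metres is added to the remeasured height only.  Used to
    validate parameter recovery against known truth.
    """
    from .schumacher import ADA as _ADA
    from .schumacher import GrowthPair, ada_project, gada_project

    d1 = rng.uniform(*d1_range, size=n_pairs)
    d2 = d1 + rng.uniform(*increment_range, size=n_pairs)
    if model == _ADA:
        level = rng.normal(3.3, 0.15, size=n_pairs)
        h1 = 1.3 + np.exp(level - params.beta1 / d1)
        h2 = ada_project(h1, d1, d2, params.beta1)
    else:
        x0 = rng.normal(3.9, 0.3, size=n_pairs)
        h1 = 1.3 + np.exp(x0 + (params.beta0 + params.beta1 * x0) / d1)
        h2 = gada_project(h1, d1, d2, params)
    h2 = np.maximum(h2 + rng.normal(0.0, noise_sd, size=n_pairs), 1.35)
    return [
        GrowthPair(unit_id=str(i), d1=float(d1[i]), d2=float(d2[i]),
                   h1=float(h1[i]), h2=float(h2[i]))
        for i in range(n_pairs)
    ]


def truths_to_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in truths])


def truth_alignment(
    truths: list[TruthRecord], sf_table: pd.DataFrame
) -> pd.DataFrame:
    """Correlate the generating site effect with each SF variant.

    ``sf_table`` is the long SF table (plot_id, method, model, criterion,
    value); SF values are averaged per plot within each variant before
    correlating.  Returns one row per variant with Spearman and Pearson
    coefficients — the recovery report used to validate the estimators.
    """
    from scipy import stats as sps

    truth_df = truths_to_frame(truths)[["plot_id", "site_effect"]]
    missing = set(sf_table["plot_id"]) - set(truth_df["plot_id"])
    if missing:
        raise JoinError(f"SF table has plots without truth records: {sorted(missing)[:5]}")
    rows = []
    for (method, model, criterion), grp in sf_table.groupby(
        ["method", "model", "criterion"], sort=True
    ):
        per_plot = grp.groupby("plot_id")["value"].mean().reset_index()
        merged = per_plot.merge(truth_df, on="plot_id")
        if len(merged) < 3 or merged["value"].nunique() < 2:
            rows.append(
                dict(method=method, model=model, criterion=criterion,
                     n=len(merged), spearman=np.nan, pearson=np.nan)
            )
            continue
        sp = sps.spearmanr(merged["site_effect"], merged["value"]).statistic
        pe = sps.pearsonr(merged["site_effect"], merged["value"]).statistic
        rows.append(
            dict(method=method, model=model, criterion=criterion,
                 n=len(merged), spearman=float(sp), pearson=float(pe))
        )
    return pd.DataFrame(rows)
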