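"""Domain types and delimited-table IO for permanent-plot tree inventories.

The unit of analysis is a :class:`PlotSeries`: one permanent plot observed at
two or more inventories a fixed number of years apart, with individual trees
linked across inventories by a stable ``tree_id``.  Trees below the minimum
diameter at breast height (dbh) callipering threshold (7.5 cm in the study
design this package targets) are excluded from analysis sets at read time but
counted, so input row totals always reconcile.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

CONIFER = "conifer"
BROADLEAF = "broadleaf"
LIVE = "live"
DEAD = "dead"

#: Minimum dbh (cm) for a tree to enter any analysis set.
DBH_THRESHOLD = 7.5

#: dbh shrinkage (cm) tolerated between inventories before a warning;
#: caliper remeasurement noise routinely produces small apparent shrinkage.
DBH_SHRINK_TOLERANCE = 0.5


@dataclass(frozen=True)
class TreeObservation:
    """One tree at one inventory."""

    tree_id: str
    species_code: str
    species_group: str  # CONIFER or BROADLEAF
    dbh: float  # cm
    h: float | None  # total height, m; None when not measured
    status: str  # LIVE or DEAD
    inventory_index: int  # 0-based ordinal within the plot's series
    year: int

    @property
    def has_height(self) -> bool:
        return self.h is not None and np.isfinite(self.h)


@dataclass
class PlotInventory:
    """All trees of one plot at one inventory."""

    plot_id: str
    area_m2: float
    inventory_index: int
    year: int
    trees: list[TreeObservation] = field(default_factory=list)

    @property
    def expansion_factor(self) -> float:
        """Per-hectare expansion factor 10000 / area."""
        return 10000.0 / self.area_m2

    def live_trees(self) -> list[TreeObservation]:
        return [t for t in self.trees if t.status == LIVE]


@dataclass
class PlotSeries:
    """A plot's linked inventories — the unit of site-form estimation."""

    plot_id: str
    inventories: list[PlotInventory]
    period_years: float = 5.0

    def __post_init__(self) -> None:
        self.inventories = sorted(self.inventories, key=lambda pi: pi.inventory_index)

    @property
    def n_inventories(self) -> int:
        return len(self.inventories)

    @property
    def area_m2(self) -> float:
        return self.inventories[0].area_m2

    def tree_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for inv in self.inventories:
            for t in inv.trees:
                seen.setdefault(t.tree_id, None)
        return list(seen)

    def observations(self, tree_id: str) -> dict[int, TreeObservation]:
        """Map inventory_index -> observation for one tree."""
        out: dict[int, TreeObservation] = {}
        for inv in self.inventories:
            for t in inv.trees:
                if t.tree_id == tree_id:
                    out[inv.inventory_index] = t
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for inv in self.inventories:
            for t in inv.trees:
                rows.append(
                    dict(
                        plot_id=self.plot_id,
                        tree_id=t.tree_id,
                        species_code=t.species_code,
                        species_group=t.species_group,
                        dbh=t.dbh,
                        h=t.h,
                        status=t.status,
                        inventory_index=t.inventory_index,
                        year=inv.year,
                    )
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class VolumeCoefficients:
    """Coefficients of the combined stem-plus-branch volume equation
    v = a0 * dbh^a1 * h^a2 + a3 * dbh^2 (v in m3, dbh in cm, h in m)."""

    key: str  # species code, group name, or "default"
    a0: float
    a1: float
    a2: float
    a3: float


class CoefficientTable:
    """Species-keyed volume coefficients with group-level fallback.

    Lookup is total: species code first, then species group, then the
    ``default`` entry, which must exist unless both groups are covered.
    """

    def __init__(self, entries: Iterable[VolumeCoefficients]):
        self._entries = {e.key: e for e in entries}
        groups_covered = CONIFER in self._entries and BROADLEAF in self._entries
        if "default" not in self._entries and not groups_covered:
            raise ValidationError(
                "coefficient table needs a 'default' entry or entries for "
                "both species groups"
            )

    def lookup(self, species_code: str, species_group: str) -> VolumeCoefficients:
        for key in (species_code, species_group, "default"):
            if key in self._entries:
                return self._entries[key]
        raise ValidationError(f"no coefficients for {species_code}/{species_group}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self._entries.values()])


@dataclass(frozen=True)
class ColumnMap:
    """Names of the required columns in a delimited tree table."""

    plot: str = "plot_id"
    tree: str = "tree_id"
    species: str = "species_code"
    group: str = "species_group"
    dbh: str = "dbh"
    height: str = "h"
    status: str = "status"
    year: str = "year"

    @classmethod
    def from_config(cls, mapping: Mapping[str, str]) -> "ColumnMap":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise FormatError(f"unknown column-map keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def required(self) -> list[str]:
        return [getattr(self, f.name) for f in dataclasses.fields(self)]


@dataclass
class ReadResult:
    """Outcome of :func:`read_tree_table` with reconciliation counts."""

    series: list[PlotSeries]
    n_rows: int
    n_kept: int
    n_excluded: int
    excluded: pd.DataFrame
    noncontiguous: list[tuple[str, str]]  # (plot_id, tree_id) gaps in the series


def read_config(path: str | Path) -> dict:
    """Read a YAML key-value configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def read_tree_table(
    path: str | Path,
    colmap: ColumnMap | None = None,
    *,
    area_m2: float = 2500.0,
    period_years: float = 5.0,
    dbh_min: float = DBH_THRESHOLD,
) -> ReadResult:
    """Read a delimited tree table (one row per tree per inventory).

    Rows with dbh below ``dbh_min`` are excluded from analysis sets but
    counted, so ``n_kept + n_excluded == n_rows``.  ``inventory_index`` is
    derived from the rank of ``year`` within each plot, so exports that
    enumerate inventories differently still load.
    """
    colmap = colmap or ColumnMap()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return frame_to_series(
        df, colmap, area_m2=area_m2, period_years=period_years, dbh_min=dbh_min
    )


def frame_to_series(
    df: pd.DataFrame,
    colmap: ColumnMap | None = None,
    *,
    area_m2: float = 2500.0,
    period_years: float = 5.0,
    dbh_min: float = DBH_THRESHOLD,
) -> ReadResult:
    """Assemble :class:`PlotSeries` from an in-memory tree table."""
    colmap = colmap or ColumnMap()
    missing = [c for c in colmap.required() if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")

    key_cols = [colmap.plot, colmap.tree, colmap.year]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0].tolist()
        raise ValidationError(f"duplicate (plot, tree, year) key: {first}")

    n_rows = len(df)
    below = df[colmap.dbh] < dbh_min
    excluded = df.loc[below].copy()
    kept = df.loc[~below]

    series: list[PlotSeries] = []
    noncontiguous: list[tuple[str, str]] = []
    for plot_id, pdf in kept.groupby(colmap.plot, sort=True):
        years = sorted(pdf[colmap.year].unique())
        year_rank = {y: i for i, y in enumerate(years)}
        inventories = []
        for y in years:
            idx = year_rank[y]
            ydf = pdf[pdf[colmap.year] == y]
            trees = [
                TreeObservation(
                    tree_id=str(row[colmap.tree]),
                    species_code=str(row[colmap.species]),
                    species_group=str(row[colmap.group]),
                    dbh=float(row[colmap.dbh]),
                    h=None if pd.isna(row[colmap.height]) else float(row[colmap.height]),
                    status=str(row[colmap.status]),
                    inventory_index=idx,
                    year=int(y),
                )
                for _, row in ydf.iterrows()
            ]
            inventories.append(
                PlotInventory(
                    plot_id=str(plot_id),
                    area_m2=area_m2,
                    inventory_index=idx,
                    year=int(y),
                    trees=trees,
                )
            )
        s = PlotSeries(str(plot_id), inventories, period_years=period_years)
        # flag trees absent from an interior inventory but present on both sides
        for tid in s.tree_ids():
            obs = s.observations(tid)
            idxs = sorted(obs)
            if idxs and idxs[-1] - idxs[0] + 1 > len(idxs):
                noncontiguous.append((s.plot_id, tid))
        series.append(s)

    return ReadResult(
        series=series,
        n_rows=n_rows,
        n_kept=len(kept),
        n_excluded=len(excluded),
        excluded=excluded,
        noncontiguous=noncontiguous,
    )


def write_tree_table(
    series: Sequence[PlotSeries], path: str | Path, colmap: ColumnMap | None = None
) -> None:
    """Write plot series back to a delimited table (inverse of read)."""
    colmap = colmap or ColumnMap()
    frames = [s.to_frame() for s in series]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not df.empty:
        df = df.rename(
            columns={
                "plot_id": colmap.plot,
                "tree_id": colmap.tree,
                "species_code": colmap.species,
                "species_group": colmap.group,
                "dbh": colmap.dbh,
                "h": colmap.height,
                "status": colmap.status,
                "year": colmap.year,
            }
        ).drop(columns=["inventory_index"])
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)


def read_volume_coefficients(path: str | Path) -> CoefficientTable:
    """Read a volume-coefficient CSV with columns key,a0,a1,a2,a3.

    ``key`` may be a species code, a species group (``conifer`` /
    ``broadleaf``), or ``default``.
    """
    df = pd.read_csv(path)
    required = ["key", "a0", "a1", "a2", "a3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    entries = [
        VolumeCoefficients(
            key=str(r["key"]), a0=r["a0"], a1=r["a1"], a2=r["a2"], a3=r["a3"]
        )
        for _, r in df.iterrows()
    ]
    return CoefficientTable(entries)


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # dbh_shrinkage | status_reversal | missing_height
    plot_id: str
    tree_id: str
    detail: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.issues

    def of_kind(self, kind: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.kind == kind]


def validate_series(
    series: PlotSeries, shrink_tolerance: float = DBH_SHRINK_TOLERANCE
) -> ValidationReport:
    """Report-only integrity checks on one plot series.

    Checks: dbh shrinking by more than ``shrink_tolerance`` cm between
    inventories, a dead tree recorded live later, and live trees lacking a
    height measurement.
    """
    report = ValidationReport()
    for tid in series.tree_ids():
        obs = series.observations(tid)
        idxs = sorted(obs)
        for a, b in zip(idxs[:-1], idxs[1:]):
            o1, o2 = obs[a], obs[b]
            if o2.dbh < o1.dbh - shrink_tolerance:
                report.issues.append(
                    ValidationIssue(
                        "dbh_shrinkage",
                        series.plot_id,
                        tid,
                        f"dbh {o1.dbh:.1f} -> {o2.dbh:.1f} cm "
                        f"(inventory {a} -> {b})",
                    )
                )
            if o1.status == DEAD and o2.status == LIVE:
                report.issues.append(
                    ValidationIssue(
                        "status_reversal",
                        series.plot_id,
                        tid,
                        f"dead at inventory {a}, live at {b}",
                    )
                )
        for i in idxs:
            o = obs[i]
            if o.status == LIVE and not o.has_height:
                report.issues.append(
                    ValidationIssue(
                        "missing_height",
                        series.plot_id,
                        tid,
                        f"no height at inventory {i}",
                    )
                )
    return report
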