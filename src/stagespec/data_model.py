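"""Domain types and file I/O for study designs and species incidence tables.

The study design is a network of forest plots crossing five forest
developmental stages (gap, establishment, optimum, plenter, terminal) with
three elevational zones (submontane, montane, subalpine).  Community data are
binary plot x species incidence matrices, one per taxonomic group.

Readers accept three plain-text layouts for incidence data: a wide CSV
(plots x species), a long CSV of (plot_id, species_id) presence records, and
a sparse triplet CSV with sidecar id lists.  All writers round-trip exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical order of forest developmental stages (successional order).
STAGES: tuple[str, ...] = ("gap", "establishment", "optimum", "plenter", "terminal")

#: Canonical order of elevational zones (low to high).
ZONES: tuple[str, ...] = ("submontane", "montane", "subalpine")

#: Nominal elevation bands (m a.s.l.) per zone; used for reporting only,
#: never to derive the zone (real plots fall slightly outside the bands).
ZONE_BANDS: dict[str, tuple[float, float]] = {
    "submontane": (-np.inf, 850.0),
    "montane": (850.0, 1400.0),
    "subalpine": (1400.0, np.inf),
}

STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}
ZONE_INDEX = {z: i for i, z in enumerate(ZONES)}

PLOT_COLUMNS = ["plot_id", "stage", "zone", "elevation_m", "x_m", "y_m",
                "spatial_group", "day_of_year"]
REQUIRED_PLOT_COLUMNS = ["plot_id", "stage", "zone", "elevation_m", "x_m", "y_m"]


class SchemaError(ValueError):
    """A required column is missing or a file layout is malformed."""


class IntegrityError(ValueError):
    """Duplicate identifiers or cross-references that do not resolve."""


# ---------------------------------------------------------------------------
# Plot records and designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlotRecord:
    """One circular study plot.

    Parameters
    ----------
    plot_id : str
        Unique identifier.
    stage : str
        Forest developmental stage, one of :data:`STAGES`.
    zone : str
        Elevational zone, one of :data:`ZONES`.
    elevation_m : float
        Elevation of the plot centre, metres a.s.l.
    x_m, y_m : float
        Projected planar coordinates in metres (UTM-like).
    spatial_group : str
        Label grouping neighbouring plots; used for random intercepts.
    day_of_year : int or None
        Optional sampling day (1-366).
    """

    plot_id: str
    stage: str
    zone: str
    elevation_m: float
    x_m: float
    y_m: float
    spatial_group: str = "g0"
    day_of_year: int | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGE_INDEX:
            raise ValueError(f"unknown stage {self.stage!r} for plot {self.plot_id!r}")
        if self.zone not in ZONE_INDEX:
            raise ValueError(f"unknown zone {self.zone!r} for plot {self.plot_id!r}")
        if self.day_of_year is not None and not 1 <= int(self.day_of_year) <= 366:
            raise ValueError(f"day_of_year {self.day_of_year} out of range for "
                             f"plot {self.plot_id!r}")


@dataclass(frozen=True)
class Design:
    """An ordered collection of :class:`PlotRecord` forming a study design."""

    plots: tuple[PlotRecord, ...]

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate plot_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.plots)

    @property
    def plot_ids(self) -> tuple[str, ...]:
        return tuple(p.plot_id for p in self.plots)

    def __getitem__(self, plot_id: str) -> PlotRecord:
        for p in self.plots:
            if p.plot_id == plot_id:
                return p
        raise KeyError(plot_id)

    def zone_plots(self, zone: str) -> tuple[PlotRecord, ...]:
        if zone not in ZONE_INDEX:
            raise ValueError(f"unknown zone {zone!r}")
        return tuple(p for p in self.plots if p.zone == zone)

    def cell_counts(self) -> pd.DataFrame:
        """Plots per stage x zone cell, stages as rows, zones as columns."""
        tab = pd.DataFrame(0, index=list(STAGES), columns=list(ZONES), dtype=int)
        for p in self.plots:
            tab.loc[p.stage, p.zone] += 1
        return tab

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.plots:
            rows.append({
                "plot_id": p.plot_id, "stage": p.stage, "zone": p.zone,
                "elevation_m": p.elevation_m, "x_m": p.x_m, "y_m": p.y_m,
                "spatial_group": p.spatial_group,
                "day_of_year": np.nan if p.day_of_year is None else p.day_of_year,
            })
        return pd.DataFrame(rows, columns=PLOT_COLUMNS)

    def validate(self, strict: bool = False) -> list[str]:
        """Check design invariants; returns report messages, never mutates.

        Zone/elevation band mismatches are reported, not enforced, because
        zones are ecological classifications that may deviate slightly from
        nominal elevation cutoffs.  With ``strict=True`` an elevation outside
        [600, 1800] m raises.
        """
        messages: list[str] = []
        for p in self.plots:
            lo, hi = ZONE_BANDS[p.zone]
            if not lo <= p.elevation_m < hi:
                messages.append(
                    f"plot {p.plot_id}: elevation {p.elevation_m:.0f} m outside "
                    f"nominal {p.zone} band")
            if not 600.0 <= p.elevation_m <= 1800.0:
                msg = (f"plot {p.plot_id}: elevation {p.elevation_m:.0f} m outside "
                       f"[600, 1800]")
                if strict:
                    raise ValueError(msg)
                messages.append(msg)
        return messages


def read_plots(path: str | Path, dialect: str = "csv") -> Design:
    """Read a plot metadata table.

    Stage and zone labels are case-folded and stripped before validation so
    e.g. ``"Optimum"`` is accepted.  Unknown labels, duplicate plot ids and
    missing required columns raise.
    """
    if dialect != "csv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    df = pd.read_csv(path, dtype={"plot_id": str, "spatial_group": str})
    missing = [c for c in REQUIRED_PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    if df["plot_id"].duplicated().any():
        dupes = sorted(df.loc[df["plot_id"].duplicated(), "plot_id"].unique())
        raise IntegrityError(f"duplicate plot_id(s) in {path}: {dupes}")

    plots = []
    for i, row in df.iterrows():
        stage = str(row["stage"]).strip().lower()
        zone = str(row["zone"]).strip().lower()
        if stage not in STAGE_INDEX:
            raise ValueError(f"row {i}: unknown stage label {row['stage']!r}")
        if zone not in ZONE_INDEX:
            raise ValueError(f"row {i}: unknown zone label {row['zone']!r}")
        x, y = float(row["x_m"]), float(row["y_m"])
        day = row.get("day_of_year", np.nan)
        plots.append(PlotRecord(
            plot_id=str(row["plot_id"]), stage=stage, zone=zone,
            elevation_m=float(row["elevation_m"]), x_m=x, y_m=y,
            spatial_group=str(row["spatial_group"]) if "spatial_group" in df.columns
            and pd.notna(row.get("spatial_group")) else "g0",
            day_of_year=None if pd.isna(day) else int(day),
        ))
    design = Design(tuple(plots))
    _reject_geographic_coordinates(design)
    return design


def _reject_geographic_coordinates(design: Design) -> None:
    # Planar metre coordinates are required; a table whose coordinates all fit
    # inside lon/lat ranges is almost certainly geographic and is rejected
    # rather than silently projected.
    if len(design) < 2:
        return
    xs = np.array([p.x_m for p in design.plots])
    ys = np.array([p.y_m for p in design.plots])
    if np.all(np.abs(xs) <= 180.0) and np.all(np.abs(ys) <= 90.0):
        raise ValueError(
            "coordinates look geographic (lon/lat); supply projected planar "
            "metres instead")


def write_plots(design: Design, path: str | Path) -> None:
    """Write a design as CSV; ``read_plots(write_plots(d)) == d`` exactly."""
    df = design.to_frame()
    df["day_of_year"] = df["day_of_year"].astype("Int64")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Incidence tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class IncidenceTable:
    """A binary plots x species incidence matrix for one taxonomic group.

    ``matrix[i, j] = 1`` records species ``species_ids[j]`` at plot
    ``plot_ids[i]``.  ``ground_truth`` optionally carries the generative
    parameters of a synthetic community (ignored by all analyses; used only
    for parameter-recovery tests).
    """

    taxon: str
    plot_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    matrix: np.ndarray
    ground_truth: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (len(self.plot_ids), len(self.species_ids)):
            raise ValueError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.plot_ids)} plots x {len(self.species_ids)} species")
        if m.size and not np.isin(m, (0, 1)).all():
            raise ValueError("incidence matrix entries must be 0 or 1")
        if len(set(self.plot_ids)) != len(self.plot_ids):
            raise IntegrityError("duplicate plot_ids in incidence table")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise IntegrityError("duplicate species_ids in incidence table")
        object.__setattr__(self, "matrix", m.astype(np.int8))
        self.matrix.setflags(write=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IncidenceTable):
            return NotImplemented
        return (self.taxon == other.taxon
                and self.plot_ids == other.plot_ids
                and self.species_ids == other.species_ids
                and np.array_equal(self.matrix, other.matrix))

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def richness(self) -> np.ndarray:
        """Species count per plot (row sums)."""
        return self.matrix.sum(axis=1)

    def species_set(self, plot_id: str) -> frozenset[str]:
        i = self.plot_ids.index(plot_id)
        present = np.flatnonzero(self.matrix[i])
        return frozenset(self.species_ids[j] for j in present)

    def subset_plots(self, plot_ids: Sequence[str]) -> "IncidenceTable":
        idx = [self.plot_ids.index(p) for p in plot_ids]
        return IncidenceTable(self.taxon, tuple(plot_ids), self.species_ids,
                              self.matrix[idx].copy())

    def validate_against(self, design: Design) -> None:
        """Raise if any plot id is not part of the design."""
        known = set(design.plot_ids)
        unknown = [p for p in self.plot_ids if p not in known]
        if unknown:
            raise IntegrityError(
                f"incidence plots not in design: {unknown[:5]}"
                + ("..." if len(unknown) > 5 else ""))


def incidence_from_long(taxon: str, records: Iterable[tuple[str, str]]) -> IncidenceTable:
    """Build a table from (plot_id, species_id) presence records.

    Repeated records collapse to a single presence.  Plot and species order is
    lexicographic.
    """
    recs = list(records)
    plot_ids = tuple(sorted({p for p, _ in recs}))
    species_ids = tuple(sorted({s for _, s in recs}))
    pi = {p: i for i, p in enumerate(plot_ids)}
    si = {s: i for i, s in enumerate(species_ids)}
    m = np.zeros((len(plot_ids), len(species_ids)), dtype=np.int8)
    for p, s in recs:
        m[pi[p], si[s]] = 1
    return IncidenceTable(taxon, plot_ids, species_ids, m)


def read_incidence(path: str | Path, format: str = "wide_csv",
                   taxon: str | None = None,
                   allow_abundance: bool = False) -> IncidenceTable:
    """Read an incidence table.

    Formats
    -------
    ``wide_csv``
        First column ``plot_id``, one column per species, cells 0/1.
    ``long_csv``
        Columns ``plot_id,species_id``; each row one presence.
    ``sparse_triplets``
        Columns ``row_index,col_index,value`` with sidecar id lists at
        ``<path>.plots`` and ``<path>.species`` (one id per line).

    Non-binary cells raise unless ``allow_abundance=True``, in which case
    positive abundances are thresholded to presence with a warning (every
    downstream statistic is incidence-based).
    """
    path = Path(path)
    taxon = taxon or path.stem
    if format == "wide_csv":
        df = pd.read_csv(path)
        if df.columns[0] != "plot_id":
            raise SchemaError(f"wide incidence must start with 'plot_id', "
                              f"got {df.columns[0]!r}")
        plot_ids = tuple(str(p) for p in df["plot_id"])
        species_ids = tuple(df.columns[1:])
        m = df.iloc[:, 1:].to_numpy()
        m = _coerce_binary(m, allow_abundance)
        return IncidenceTable(taxon, plot_ids, species_ids, m)
    if format == "long_csv":
        df = pd.read_csv(path, dtype=str)
        for col in ("plot_id", "species_id"):
            if col not in df.columns:
                raise SchemaError(f"long incidence requires column {col!r}")
        return incidence_from_long(taxon, zip(df["plot_id"], df["species_id"]))
    if format == "sparse_triplets":
        plots = Path(f"{path}.plots").read_text().split()
        species = Path(f"{path}.species").read_text().split()
        trip = pd.read_csv(path, header=None,
                           names=["row_index", "col_index", "value"])
        m = np.zeros((len(plots), len(species)))
        m[trip["row_index"], trip["col_index"]] = trip["value"]
        m = _coerce_binary(m, allow_abundance)
        return IncidenceTable(taxon, tuple(plots), tuple(species), m)
    raise ValueError(f"unknown incidence format {format!r}")


def _coerce_binary(m: np.ndarray, allow_abundance: bool) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if np.isnan(m).any():
        raise ValueError("incidence matrix contains missing cells")
    if np.isin(m, (0.0, 1.0)).all():
        return m.astype(np.int8)
    if not allow_abundance:
        bad = m[~np.isin(m, (0.0, 1.0))]
        raise ValueError(f"non-binary incidence cell(s), e.g. {bad.flat[0]!r}; "
                         "pass allow_abundance=True to threshold at >0")
    warnings.warn("abundance values thresholded to presence/absence (>0 -> 1)",
                  stacklevel=3)
    return (m > 0).astype(np.int8)


def write_incidence(inc: IncidenceTable, path: str | Path,
                    format: str = "wide_csv") -> None:
    """Write an incidence table; exact round trip with :func:`read_incidence`."""
    path = Path(path)
    if format == "wide_csv":
        df = pd.DataFrame(inc.matrix, columns=list(inc.species_ids))
        df.insert(0, "plot_id", list(inc.plot_ids))
        df.to_csv(path, index=False)
    elif format == "long_csv":
        rows, cols = np.nonzero(inc.matrix)
        df = pd.DataFrame({
            "plot_id": [inc.plot_ids[i] for i in rows],
            "species_id": [inc.species_ids[j] for j in cols],
        })
        df.to_csv(path, index=False)
    elif format == "sparse_triplets":
        rows, cols = np.nonzero(inc.matrix)
        pd.DataFrame({"r": rows, "c": cols, "v": 1}).to_csv(
            path, index=False, header=False)
        Path(f"{path}.plots").write_text("\n".join(inc.plot_ids) + "\n")
        Path(f"{path}.species").write_text("\n".join(inc.species_ids) + "\n")
    else:
        raise ValueError(f"unknown incidence format {format!r}")
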