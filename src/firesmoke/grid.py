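"""Regular model grid geometry and the centroid rule.

A chemical-transport model reports concentrations on a regular projected
grid (e.g. 12-km cells). Administrative-unit statistics use the *centroid
rule*: a cell contributes to a unit if and only if the cell's centroid lies
within the unit's polygon. Cells whose centroid falls in no polygon are kept
as "unassigned"; units that capture no centroid are flagged "empty" (such a
unit ends up with no model data at all — this happens in practice for units
smaller than one grid cell).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

__all__ = [
    "GridDefinition",
    "AdminUnit",
    "CellAssignment",
    "build_grid",
    "assign_cells_to_units",
    "read_units_geojson",
    "write_units_geojson",
]


@dataclass(frozen=True)
class GridDefinition:
    """Regular projected grid.

    ``origin_x``/``origin_y`` are the coordinates (m) of the lower-left
    corner of cell (col=0, row=0); the centroid of cell (c, r) is
    ``(origin_x + (c + 0.5) * cell_size, origin_y + (r + 0.5) * cell_size)``.
    Coordinates are planar; no geodesic computation is done.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_cols: int
    n_rows: int
    crs_label: str = "local-planar"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.n_cols}x{self.n_rows}"
            )

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid rectangle."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def centroid(self, col: int, row: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y + (row + 0.5) * self.cell_size,
        )

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Centroid coordinate arrays ``(X, Y)``, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_containing(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell (col, row) whose half-open rectangle [left,right)x[bottom,top)
        contains the point, or None if the point is outside the grid extent."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((y - self.origin_y) / self.cell_size))
        if 0 <= col < self.n_cols and 0 <= row < self.n_rows:
            return col, row
        return None

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_size": self.cell_size,
            "n_cols": self.n_cols,
            "n_rows": self.n_rows,
            "crs_label": self.crs_label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridDefinition":
        return cls(**{k: d[k] for k in (
            "origin_x", "origin_y", "cell_size", "n_cols", "n_rows", "crs_label")})


def build_grid(
    origin_x: float,
    origin_y: float,
    cell_size: float,
    n_cols: int,
    n_rows: int,
    crs_label: str = "local-planar",
) -> GridDefinition:
    """Construct a :class:`GridDefinition` (validates dimensions and cell size)."""
    return GridDefinition(origin_x, origin_y, cell_size, n_cols, n_rows, crs_label)


@dataclass(frozen=True)
class AdminUnit:
    """Administrative unit: a (multi)polygon in grid coordinates."""

    unit_id: str
    name: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError(f"unit {self.unit_id!r}: invalid polygon geometry")


@dataclass
class CellAssignment:
    """Result of the centroid rule over one grid and one unit collection."""

    mapping: dict[tuple[int, int], str]
    unassigned: set[tuple[int, int]]
    empty_units: set[str]
    unit_ids: tuple[str, ...] = field(default_factory=tuple)

    def cells_of(self, unit_id: str) -> list[tuple[int, int]]:
        return sorted(c for c, u in self.mapping.items() if u == unit_id)

    def cell_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {u: 0 for u in self.unit_ids}
        for u in self.mapping.values():
            counts[u] = counts.get(u, 0) + 1
        return counts


def assign_cells_to_units(
    grid: GridDefinition, units: Sequence[AdminUnit]
) -> CellAssignment:
    """Assign every grid cell to the unit containing its centroid.

    A centroid sitting exactly on a shared boundary (covered by several
    polygons) is assigned to the unit whose ``unit_id`` sorts first
    lexicographically, with a warning; this makes the result deterministic
    and independent of input order. Cells covered by no polygon are
    unassigned; units that capture no centroid are flagged empty.
    """
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate unit_id(s): {dupes}")

    xs, ys = grid.centroids()
    cells = [(c, r) for r in range(grid.n_rows) for c in range(grid.n_cols)]
    points = shapely.points(
        [xs[r, c] for c, r in cells], [ys[r, c] for c, r in cells]
    )

    tree = STRtree([u.geometry for u in units])
    # covers (not contains): a centroid on a polygon boundary still belongs
    # to that polygon, and the tie-break below resolves shared boundaries.
    pt_idx, unit_idx = tree.query(points, predicate="covered_by")

    candidates: dict[int, list[str]] = {}
    for pi, ui in zip(pt_idx.tolist(), unit_idx.tolist()):
        candidates.setdefault(pi, []).append(units[ui].unit_id)

    assignment: dict[tuple[int, int], str] = {}
    unassigned: set[tuple[int, int]] = set()
    n_ties = 0
    for i, cell in enumerate(cells):
        hits = candidates.get(i)
        if not hits:
            unassigned.add(cell)
        elif len(hits) == 1:
            assignment[cell] = hits[0]
        else:
            n_ties += 1
            assignment[cell] = min(hits)
    if n_ties:
        warnings.warn(
            f"{n_ties} cell centroid(s) covered by more than one unit; "
            "assigned to the lexicographically first unit_id",
            stacklevel=2,
        )

    assigned_units = set(assignment.values())
    empty = {u.unit_id for u in units} - assigned_units
    if empty:
        logger.info("units with no assigned cells: %s", sorted(empty))
    return CellAssignment(
        mapping=assignment,
        unassigned=unassigned,
        empty_units=empty,
        unit_ids=tuple(ids),
    )


def read_units_geojson(path: str | Path) -> list[AdminUnit]:
    """Read an AdminUnit collection from a GeoJSON FeatureCollection.

    Features must carry ``unit_id`` and ``name`` properties; geometries are
    interpreted in the grid's planar coordinate system.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    units = []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if "unit_id" not in props or "name" not in props:
            raise ValueError(
                f"{path}: every feature needs 'unit_id' and 'name' properties"
            )
        units.append(
            AdminUnit(
                unit_id=str(props["unit_id"]),
                name=str(props["name"]),
                geometry=shape(feat["geometry"]),
            )
        )
    return units


def write_units_geojson(
    units: Iterable[AdminUnit],
    path: str | Path,
    extra_properties: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Write units as GeoJSON; ``extra_properties[unit_id]`` adds per-unit
    attributes (used to join smokewave counts or exposure classes for maps)."""
    features = []
    for u in units:
        props: dict[str, object] = {"unit_id": u.unit_id, "name": u.name}
        if extra_properties and u.unit_id in extra_properties:
            props.update(extra_properties[u.unit_id])
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(u.geometry)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
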