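"""Analysis grid construction and range rasterization.

The analysis grid tiles a projected (equal-area, by convention Mollweide)
extent with square cells of a fixed resolution; species ranges are turned
into a binary presence matrix by testing whether any of a species' polygons
covers the cell *center* (boundary contact counts as presence).  Cell-level
richness is the per-group row sum of the presence matrix, and cells with
fewer than three species are excluded from statistical analyses to limit
sampling bias.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "Grid",
    "PresenceMatrix",
    "build_grid",
    "rasterize_ranges",
    "richness_and_filter",
    "mollweide",
]


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Specification of the analysis grid.

    ``extent`` is ``(xmin, ymin, xmax, ymax)`` in the working coordinate
    system; ``resolution`` the cell edge in the same units (2 "degrees" for
    the canonical ~220 km equal-area design); ``projection`` a free-form
    identifier recorded in outputs (``"mollweide"`` by default).
    """

    resolution: float = 2.0
    extent: tuple[float, float, float, float] = (-180.0, -90.0, 180.0, 90.0)
    projection: str = "mollweide"

    def __post_init__(self) -> None:
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("extent must be nonempty")
        if (xmax - xmin) < self.resolution or (ymax - ymin) < self.resolution:
            raise ValueError("extent smaller than one cell")

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) cell counts; the last row/column may overshoot the extent."""
        xmin, ymin, xmax, ymax = self.extent
        nx = math.ceil((xmax - xmin) / self.resolution - 1e-9)
        ny = math.ceil((ymax - ymin) / self.resolution - 1e-9)
        return ny, nx


@dataclasses.dataclass(frozen=True)
class Grid:
    """Materialized grid: cell polygons and centroids, row-major order."""

    spec: GridSpec
    cells: pd.DataFrame  # columns: cell, geometry, cx, cy

    @property
    def centroids(self) -> np.ndarray:
        return self.cells[["cx", "cy"]].to_numpy()


@dataclasses.dataclass(frozen=True)
class PresenceMatrix:
    """Binary cell x species matrix with the cell centroids alongside."""

    matrix: pd.DataFrame  # index: cell ids; columns: species ids; values 0/1
    centroids: pd.DataFrame  # index: cell ids; columns cx, cy

    def __post_init__(self) -> None:
        values = self.matrix.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("presence matrix must be binary")
        if not self.matrix.index.equals(self.centroids.index):
            raise ValueError("every cell must map to exactly one centroid")


def build_grid(spec: GridSpec) -> Grid:
    """Tile the extent with contiguous, non-overlapping square cells.

    Cells are ordered row-major from the lower-left corner (y outer, x
    inner); ``cell`` ids are ``"r{row}c{col}"`` and centroids are the cell
    centers.
    """
    ny, nx = spec.shape
    xmin, ymin, _, _ = spec.extent
    res = spec.resolution
    rows = []
    for j in range(ny):
        for i in range(nx):
            x0, y0 = xmin + i * res, ymin + j * res
            rows.append(
                {
                    "cell": f"r{j}c{i}",
                    "geometry": box(x0, y0, x0 + res, y0 + res),
                    "cx": x0 + res / 2.0,
                    "cy": y0 + res / 2.0,
                }
            )
    return Grid(spec=spec, cells=pd.DataFrame(rows))


def rasterize_ranges(
    ranges: Mapping[str, BaseGeometry], grid: Grid
) -> PresenceMatrix:
    """Rasterize species range polygons onto the grid by centroid membership.

    A species is present in a cell iff any component of its (multi)polygon
    covers the cell center; boundary contact counts as presence
    (deterministic tie-break).  Invalid polygons are repaired with
    ``make_valid``; species whose geometry cannot be repaired are skipped
    with a log entry.  Ranges and grid must share a coordinate reference.
    """
    points = shapely.points(grid.cells["cx"].to_numpy(), grid.cells["cy"].to_numpy())
    columns: dict[str, np.ndarray] = {}
    for species, geom in ranges.items():
        if geom is None or geom.is_empty:
            logger.warning("species %s has an empty range; skipped", species)
            columns[species] = np.zeros(len(points), dtype=np.int8)
            continue
        if not geom.is_valid:
            logger.warning("species %s has an invalid polygon; repairing", species)
            try:
                geom = make_valid(geom)
            except Exception:  # pragma: no cover - shapely repair failure
                logger.warning("species %s could not be repaired; skipped", species)
                columns[species] = np.zeros(len(points), dtype=np.int8)
                continue
        columns[species] = shapely.covers(geom, points).astype(np.int8)
    matrix = pd.DataFrame(columns, index=grid.cells["cell"])
    centroids = grid.cells.set_index("cell")[["cx", "cy"]]
    return PresenceMatrix(matrix=matrix, centroids=centroids)


def richness_and_filter(
    presence: PresenceMatrix | pd.DataFrame,
    min_species: int = 3,
    groups: Mapping[str, str] | pd.Series | None = None,
    mode: str = "per_group",
) -> tuple[pd.DataFrame, dict[str, pd.Index]]:
    """Per-cell species richness and the cells passing the richness filter.

    Richness is the row sum of the presence matrix per taxon group (one
    ``total`` pseudo-group when no grouping is given); cells with fewer than
    ``min_species`` species in a group are dropped from that group's
    analysis.  With ``mode="intersection"`` every group's retained set is the
    intersection over groups (cells adequate for all groups at once).

    Returns ``(richness, retained)`` where ``richness`` is a cell x group
    DataFrame and ``retained`` maps group -> retained cell index.
    """
    matrix = presence.matrix if isinstance(presence, PresenceMatrix) else presence
    if matrix.shape[1] == 0:
        empty = pd.DataFrame(index=matrix.index)
        return empty, {}
    if groups is None:
        richness = matrix.sum(axis=1).to_frame("total")
    else:
        groups = pd.Series(groups)
        richness = matrix.T.groupby(groups.reindex(matrix.columns)).sum().T
    retained = {g: richness.index[richness[g] >= min_species] for g in richness.columns}
    if mode == "intersection":
        common = richness.index
        for idx in retained.values():
            common = common.intersection(idx)
        retained = {g: common for g in retained}
    elif mode != "per_group":
        raise ValueError(f"unknown filter mode {mode!r}")
    return richness, retained


def mollweide(
    lon: np.ndarray, lat: np.ndarray, radius: float = 6371007.181
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Mollweide projection (equal-area) for lon/lat in degrees.

    Solves ``2 theta + sin(2 theta) = pi sin(phi)`` by Newton iteration.
    Returned coordinates are in meters on a sphere of authalic radius.
    Provided as a convenience for projecting real-world coordinates; the
    synthetic pipeline works directly in projected units.
    """
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    theta = np.array(phi, copy=True)
    target = np.pi * np.sin(phi)
    for _ in range(50):
        f = 2.0 * theta + np.sin(2.0 * theta) - target
        fp = 2.0 + 2.0 * np.cos(2.0 * theta)
        step = np.where(np.abs(fp) > 1e-12, f / np.maximum(fp, 1e-12), 0.0)
        theta = theta - step
        if np.all(np.abs(step) < 1e-12):
            break
    x = radius * (2.0 * math.sqrt(2.0) / np.pi) * lam * np.cos(theta)
    y = radius * math.sqrt(2.0) * np.sin(theta)
    return x, y
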