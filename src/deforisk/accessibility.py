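"""Elevation-aware path distance from forest edges (or roads) into forest.

Movement is restricted to forest cells plus the source cells themselves —
distances measure penetration into forest from its access points.  The
lattice is 8-connected; a step between neighboring cell centers costs the
surface length ``sqrt(horizontal² + Δelevation²)`` where the horizontal
component is ``cell_size`` for axial moves and ``cell_size·√2`` for diagonal
moves.  This is a documented desk-scale approximation of a GIS path-distance
operator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grids import GridSpec
from .habitat import EshResult

__all__ = [
    "DistanceRaster",
    "AccessResult",
    "forest_edges",
    "path_distance",
    "fraction_within",
    "road_sources",
]

DEFAULT_ACCESS_THRESHOLD_M = 5000.0

# (di, dj, horizontal multiplier): 8-neighborhood, each undirected pair once
_STEPS = (
    (0, 1, 1.0),
    (1, 0, 1.0),
    (1, 1, np.sqrt(2.0)),
    (1, -1, np.sqrt(2.0)),
)


@dataclass
class DistanceRaster:
    """Per-cell distance (metres) to the nearest source; ∞ where unreachable."""

    grid: GridSpec
    distance: np.ndarray

    def __post_init__(self) -> None:
        self.grid.validate_raster(self.distance, "distance")


@dataclass
class AccessResult:
    """Fraction of a species' habitat within ``threshold_m`` of a source."""

    species_id: str
    threshold_m: float
    fraction_within: float
    undefined: bool = False


def forest_edges(forest: np.ndarray) -> np.ndarray:
    """Forest cells with at least one non-forest 4-neighbor.

    The raster border counts as non-forest, so forest touching the border is
    edge.
    """
    forest = forest.astype(bool)
    padded = np.pad(forest, 1, constant_values=False)
    interior_neighbors = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return forest & ~interior_neighbors


def path_distance(
    forest: np.ndarray,
    elevation: np.ndarray,
    sources: np.ndarray,
    grid: GridSpec,
) -> DistanceRaster:
    """Multi-source shortest path distance over forest (plus source) cells.

    Returns ∞ outside the traversable set and wherever no source is
    reachable; exactly 0 at source cells.  With an empty source set every
    cell is ∞ and a warning is emitted.
    """
    grid.validate_raster(forest, "forest")
    grid.validate_raster(elevation, "elevation")
    grid.validate_raster(sources, "sources")
    if not np.all(np.isfinite(elevation)):
        raise ValueError("elevation must be finite everywhere")

    traversable = forest.astype(bool) | sources.astype(bool)
    distance = np.full(grid.shape, np.inf)
    if not sources.any():
        warnings.warn("no source cells: all distances are infinite", stacklevel=2)
        return DistanceRaster(grid, distance)

    node_id = np.full(grid.shape, -1, dtype=np.int64)
    rows, cols = np.nonzero(traversable)
    node_id[rows, cols] = np.arange(rows.size)

    senders, receivers, weights = [], [], []
    for di, dj, mult in _STEPS:
        a = _shift_valid(traversable, di, dj)
        if not a.any():
            continue
        i, j = np.nonzero(a)
        dz = elevation[i + di, j + dj] - elevation[i, j]
        w = np.hypot(mult * grid.cell_size, dz)
        senders.append(node_id[i, j])
        receivers.append(node_id[i + di, j + dj])
        weights.append(w)

    n = rows.size
    if senders:
        graph = coo_matrix(
            (np.concatenate(weights), (np.concatenate(senders), np.concatenate(receivers))),
            shape=(n, n),
        ).tocsr()
    else:
        graph = coo_matrix((n, n)).tocsr()

    source_ids = node_id[sources.astype(bool)]
    dist = dijkstra(graph, directed=False, indices=source_ids, min_only=True)
    distance[rows, cols] = dist
    return DistanceRaster(grid, distance)


def _shift_valid(traversable: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Cells whose (di, dj) neighbor exists and is also traversable."""
    ok = np.zeros_like(traversable)
    n_rows, n_cols = traversable.shape
    i0, i1 = max(0, -di), min(n_rows, n_rows - di)
    j0, j1 = max(0, -dj), min(n_cols, n_cols - dj)
    ok[i0:i1, j0:j1] = traversable[i0:i1, j0:j1] & traversable[
        i0 + di : i1 + di, j0 + dj : j1 + dj
    ]
    return ok


def fraction_within(
    esh: EshResult,
    dist: DistanceRaster,
    threshold_m: float = DEFAULT_ACCESS_THRESHOLD_M,
) -> AccessResult:
    """Fraction of ESH cells whose path distance is ≤ ``threshold_m``."""
    if esh.mask.shape != dist.distance.shape:
        raise ValueError("ESH and distance raster are on different grids")
    n_cells = int(np.count_nonzero(esh.mask))
    if n_cells == 0:
        return AccessResult(esh.species_id, threshold_m, float("nan"), undefined=True)
    n_within = int(np.count_nonzero(esh.mask & (dist.distance <= threshold_m)))
    return AccessResult(esh.species_id, threshold_m, n_within / n_cells)


def road_sources(
    roads: Optional[np.ndarray],
    forest: np.ndarray,
    major_mask: Optional[np.ndarray] = None,
    major_only: bool = False,
) -> np.ndarray:
    """Source mask for road-based accessibility.

    ``major_mask`` (⊆ roads) flags the major-road subset; with
    ``major_only`` the sources shrink to that subset.  Downstream use is
    identical to forest-edge sources.
    """
    if roads is None:
        raise ValueError("roads layer is required for road-based accessibility")
    roads = roads.astype(bool)
    if roads.shape != forest.shape:
        raise ValueError("roads and forest rasters are on different grids")
    if major_only:
        if major_mask is None:
            raise ValueError("major_only requires a major-road mask")
        return roads & major_mask.astype(bool)
    return roads
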