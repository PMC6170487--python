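"""Extent of suitable habitat (ESH), habitat change, and convex-hull EOO.

ESH is the species' range intersected with forest cover and, when elevation
limits are known, with the band ``elev_min <= elevation <= elev_max``
(inclusive on both ends).  Species without elevation limits skip the
elevation clip.  Habitat change between two dates is summarized by the
fractional loss ``p_loss = (area_t0 - area_t1) / area_t0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry

from .grids import GridSpec, rasterize_geometry

__all__ = [
    "PERSECUTION_LEVELS",
    "SpeciesRecord",
    "EshResult",
    "HabitatChange",
    "compute_esh",
    "habitat_change",
    "eoo_convex_hull",
]

PERSECUTION_LEVELS = ("none", "low", "medium", "high")


@dataclass
class SpeciesRecord:
    """One species: range geometry plus assessment traits.

    ``elev_min``/``elev_max`` and ``generation_length`` may be ``None`` when
    unknown; the pipeline then skips the elevation clip and falls back to the
    10-year assessment window, respectively.
    """

    species_id: str
    range_geometry: BaseGeometry
    elev_min: Optional[float] = None
    elev_max: Optional[float] = None
    generation_length: Optional[float] = None
    persecution: str = "none"
    forest_dependent: bool = True

    def __post_init__(self) -> None:
        if self.persecution not in PERSECUTION_LEVELS:
            raise ValueError(f"unknown persecution category: {self.persecution!r}")
        if (
            self.elev_min is not None
            and self.elev_max is not None
            and self.elev_min > self.elev_max
        ):
            raise ValueError("elev_min must not exceed elev_max")
        if self.range_geometry.is_empty or self.range_geometry.area <= 0:
            raise ValueError(f"species {self.species_id}: range area must be > 0")

    @property
    def has_elevation_limits(self) -> bool:
        return self.elev_min is not None or self.elev_max is not None


@dataclass
class EshResult:
    """Suitable-habitat mask and area for one species at one date."""

    species_id: str
    date_label: str
    mask: np.ndarray
    area_km2: float

    @classmethod
    def from_mask(
        cls, species_id: str, date_label: str, mask: np.ndarray, grid: GridSpec
    ) -> "EshResult":
        grid.validate_raster(mask, "esh mask")
        area = float(np.count_nonzero(mask)) * grid.cell_area_km2
        return cls(species_id, date_label, mask.astype(bool), area)


@dataclass
class HabitatChange:
    """Habitat areas at the two dates and the fractional loss between them.

    ``p_loss`` is NaN (and ``undefined`` is set) when the species had no
    habitat at t0; a negative ``p_loss`` marks a habitat increase.
    """

    species_id: str
    area_t0_km2: float
    area_t1_km2: float
    p_loss: float = field(init=False)
    increase: bool = field(init=False)
    undefined: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.area_t0_km2 > 0:
            self.p_loss = (self.area_t0_km2 - self.area_t1_km2) / self.area_t0_km2
            self.undefined = False
        else:
            self.p_loss = float("nan")
            self.undefined = True
        self.increase = (not self.undefined) and self.p_loss < 0


def compute_esh(
    species: SpeciesRecord,
    forest: np.ndarray,
    elevation: np.ndarray,
    grid: GridSpec,
    date_label: str = "t",
    range_mask: Optional[np.ndarray] = None,
) -> EshResult:
    """Compute the extent of suitable habitat for one species.

    The mask is ``rasterized_range AND forest AND elevation_band``.  Pass a
    precomputed ``range_mask`` to avoid re-rasterizing the same geometry for
    several dates.  A species whose rasterized range is empty yields a
    zero-area result with a warning rather than an error.
    """
    grid.validate_raster(forest, "forest")
    grid.validate_raster(elevation, "elevation")
    if range_mask is None:
        range_mask = rasterize_geometry(species.range_geometry, grid)
    else:
        grid.validate_raster(range_mask, "range mask")
    if not range_mask.any():
        warnings.warn(
            f"species {species.species_id}: rasterized range is empty",
            stacklevel=2,
        )
    mask = range_mask & forest.astype(bool)
    if species.elev_min is not None:
        mask &= elevation >= species.elev_min
    if species.elev_max is not None:
        mask &= elevation <= species.elev_max
    return EshResult.from_mask(species.species_id, date_label, mask, grid)


def habitat_change(esh_t0: EshResult, esh_t1: EshResult) -> HabitatChange:
    """Fractional habitat loss between two ESH results for the same species."""
    if esh_t0.species_id != esh_t1.species_id:
        raise ValueError("habitat_change requires results for the same species")
    if esh_t0.mask.shape != esh_t1.mask.shape:
        raise ValueError("ESH masks are on different grids")
    return HabitatChange(esh_t0.species_id, esh_t0.area_km2, esh_t1.area_km2)


def eoo_convex_hull(
    occupied: np.ndarray | BaseGeometry, grid: Optional[GridSpec] = None
) -> float:
    """Extent of occurrence (km²): area of the minimum convex hull.

    Accepts either a boolean occupancy raster (hull of occupied cell
    centers; requires ``grid``) or a geometry (hull of its vertices).
    Degenerate hulls (a single point or collinear points) have zero area.
    """
    if isinstance(occupied, BaseGeometry):
        if occupied.is_empty:
            raise ValueError("cannot compute EOO of an empty geometry")
        return shapely.convex_hull(occupied).area / 1e6
    if grid is None:
        raise ValueError("grid is required when passing an occupancy raster")
    grid.validate_raster(occupied, "occupancy")
    rows, cols = np.nonzero(occupied)
    if rows.size == 0:
        raise ValueError("cannot compute EOO of an empty occupancy raster")
    x0, y0 = grid.origin
    xs = x0 + (cols + 0.5) * grid.cell_size
    ys = y0 + (rows + 0.5) * grid.cell_size
    hull = MultiPoint(np.column_stack([xs, ys])).convex_hull
    return hull.area / 1e6
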