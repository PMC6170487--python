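"""Protected-area coverage of species habitat, including the hunting-safe core.

Coverage is the intersection of a species' suitable habitat with the
protected mask; core coverage further restricts to cells beyond a trapper
penetration threshold (default 5 km) from the forest edge.  Flags mark
species whose core protected habitat falls at or below the 2000 km²
restricted-range threshold and below the 10 km² threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .accessibility import DistanceRaster
from .habitat import EshResult
from .grids import GridSpec

__all__ = ["ProtectionResult", "pa_coverage", "core_pa_coverage", "protection_result"]

VU_AREA_KM2 = 2000.0
CR_AREA_KM2 = 10.0


@dataclass
class ProtectionResult:
    species_id: str
    esh_km2: float
    esh_in_pa_km2: float
    fraction_in_pa: float
    core_in_pa_km2: float
    fraction_core_in_pa: float
    below_vu_threshold: bool  # core protected habitat <= 2000 km²
    below_cr_threshold: bool  # core protected habitat < 10 km²
    undefined: bool = False


def _area_and_fraction(
    esh: EshResult, selected: np.ndarray, grid: GridSpec
) -> Tuple[float, float]:
    n_esh = int(np.count_nonzero(esh.mask))
    area = float(np.count_nonzero(selected)) * grid.cell_area_km2
    fraction = area / esh.area_km2 if n_esh else float("nan")
    return area, fraction


def pa_coverage(
    esh: EshResult, protected: np.ndarray, grid: GridSpec
) -> Tuple[float, float]:
    """(km², fraction of ESH) inside protected areas."""
    grid.validate_raster(protected, "protected")
    if esh.mask.shape != protected.shape:
        raise ValueError("ESH and protected rasters are on different grids")
    return _area_and_fraction(esh, esh.mask & protected.astype(bool), grid)


def core_pa_coverage(
    esh: EshResult,
    protected: np.ndarray,
    dist: DistanceRaster,
    grid: GridSpec,
    threshold_m: float = 5000.0,
) -> Tuple[float, float]:
    """(km², fraction) of protected ESH beyond ``threshold_m`` from the edge.

    At threshold 0 this equals :func:`pa_coverage` because source cells are
    the only cells at distance exactly 0.
    """
    grid.validate_raster(protected, "protected")
    grid.validate_raster(dist.distance, "distance")
    if threshold_m == 0:
        # degenerate threshold: nothing is excluded, not even distance-0 cells
        selected = esh.mask & protected.astype(bool)
    else:
        selected = esh.mask & protected.astype(bool) & (dist.distance > threshold_m)
    return _area_and_fraction(esh, selected, grid)


def protection_result(
    esh: EshResult,
    protected: np.ndarray,
    dist: DistanceRaster,
    grid: GridSpec,
    threshold_m: float = 5000.0,
    vu_area_km2: float = VU_AREA_KM2,
    cr_area_km2: float = CR_AREA_KM2,
) -> ProtectionResult:
    """Full per-species protection summary with threshold flags."""
    pa_km2, pa_frac = pa_coverage(esh, protected, grid)
    core_km2, core_frac = core_pa_coverage(esh, protected, dist, grid, threshold_m)
    empty = not esh.mask.any()
    return ProtectionResult(
        species_id=esh.species_id,
        esh_km2=esh.area_km2,
        esh_in_pa_km2=pa_km2,
        fraction_in_pa=pa_frac,
        core_in_pa_km2=core_km2,
        fraction_core_in_pa=core_frac,
        below_vu_threshold=core_km2 <= vu_area_km2,
        below_cr_threshold=core_km2 < cr_area_km2,
        undefined=empty,
    )
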