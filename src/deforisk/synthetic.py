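"""Seeded synthetic landscapes and species sets with known ground truth.

A landscape is a stack of aligned equal-area rasters: forest at two dates,
elevation, a two-country partition, protected areas (polygons with IUCN-style
categories) and optional roads.  Islands are smoothed random blobs on a sea
background; forest loss between the two dates is sampled without replacement
with cell weights ``exp(-edge_bias * distance_to_edge / cell_size)``, so
larger ``edge_bias`` concentrates clearing nearer the forest edge and
``edge_bias = 0`` clears uniformly.

Everything is driven by a single integer seed; identical configurations
produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Polygon

from .grids import GridSpec, rasterize_geometry, write_raster
from .habitat import PERSECUTION_LEVELS, SpeciesRecord

__all__ = [
    "SyntheticConfig",
    "LandscapeStack",
    "generate_landscape",
    "generate_species",
    "cleared_cells",
    "realized_loss_fraction",
]

# IUCN-style PA categories; only I–V count toward the protected mask.
PA_CATEGORIES_KEPT = ("I", "II", "III", "IV", "V")
PA_CATEGORIES_ALL = PA_CATEGORIES_KEPT + ("VI",)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic landscape and species generator.

    All fractions are in [0, 1].  ``forest_fraction`` is the t0 forest share
    of land cells; ``loss_fraction`` is the share of t0 forest cleared by t1.
    Radii are expressed as fractions of the smaller grid dimension.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 1000.0  # 200 km domain: EOO/PA thresholds stay meaningful
    n_islands: int = 3
    island_radius_range: Tuple[float, float] = (0.10, 0.22)
    forest_fraction: float = 0.8
    loss_fraction: float = 0.2
    edge_bias: float = 2.0
    relief: float = 1500.0
    pa_fraction: float = 0.15
    country_a_fraction: float = 0.6
    n_species: int = 30
    range_radius_range: Tuple[float, float] = (0.06, 0.30)
    persecution_probs: Tuple[float, float, float, float] = (0.5, 0.2, 0.15, 0.15)
    elevation_limit_prob: float = 0.7
    generation_length_range: Tuple[float, float] = (1.0, 8.0)
    missing_generation_prob: float = 0.1
    years_between: float = 15.0
    with_roads: bool = False
    n_roads: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "forest_fraction",
            "loss_fraction",
            "pa_fraction",
            "country_a_fraction",
            "elevation_limit_prob",
            "missing_generation_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.persecution_probs) - 1.0) > 1e-9:
            raise ValueError("persecution_probs must sum to 1")
        if self.edge_bias < 0:
            raise ValueError("edge_bias must be >= 0")
        if self.forest_fraction == 0.0 and self.loss_fraction > 0.0:
            raise ValueError("cannot lose forest from a forestless landscape")

    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size)


@dataclass
class LandscapeStack:
    """Aligned raster layers sharing one grid, plus the source polygons."""

    grid: GridSpec
    forest_t0: np.ndarray
    forest_t1: np.ndarray
    elevation: np.ndarray
    country_a: np.ndarray
    protected: np.ndarray
    land: np.ndarray
    roads: Optional[np.ndarray] = None
    roads_major: Optional[np.ndarray] = None
    years_between: float = 15.0
    island_polygons: List[Polygon] = field(default_factory=list)
    pa_polygons: List[Tuple[Polygon, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("forest_t0", "forest_t1", "elevation", "country_a", "protected", "land"):
            self.grid.validate_raster(getattr(self, name), name)
        if np.any(self.forest_t1 & ~self.forest_t0):
            raise ValueError("forest_t1 must be a subset of forest_t0")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("elevation must be finite everywhere")

    def write(self, out_dir: str | Path, fmt: str = "asc") -> Dict[str, Path]:
        """Write every raster layer to ``out_dir``; returns name → path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        layers = {
            "forest_t0": self.forest_t0,
            "forest_t1": self.forest_t1,
            "elevation": self.elevation,
            "country_a": self.country_a,
            "protected": self.protected,
            "land": self.land,
        }
        if self.roads is not None:
            layers["roads"] = self.roads
            layers["roads_major"] = self.roads_major
        return {
            name: write_raster(out_dir / f"{name}.{fmt}", arr, self.grid)
            for name, arr in layers.items()
        }


def cleared_cells(stack: LandscapeStack) -> np.ndarray:
    """Cells that were forest at t0 but not at t1."""
    return stack.forest_t0 & ~stack.forest_t1


def realized_loss_fraction(stack: LandscapeStack) -> float:
    n_t0 = int(np.count_nonzero(stack.forest_t0))
    if n_t0 == 0:
        return 0.0
    return int(np.count_nonzero(cleared_cells(stack))) / n_t0


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------


def _rng_for(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage from the single config seed
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _blob_polygon(
    rng: np.random.Generator,
    center: Tuple[float, float],
    radius: float,
    roughness: float = 0.35,
    n_vertices: int = 64,
    n_harmonics: int = 4,
) -> Polygon:
    """A smoothed random blob: a circle with low-order radial harmonics."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for k in range(1, n_harmonics + 1):
        amp = roughness * rng.uniform(0.2, 1.0) / k
        phase = rng.uniform(0.0, 2.0 * np.pi)
        r += amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.2, None) * radius
    xs = center[0] + r * np.cos(theta)
    ys = center[1] + r * np.sin(theta)
    poly = Polygon(np.column_stack([xs, ys]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _smooth_noise(
    rng: np.random.Generator, shape: Tuple[int, int], sigma: float
) -> np.ndarray:
    """Gaussian-filtered white noise, rescaled to [0, 1]."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    lo, hi = noise.min(), noise.max()
    if hi == lo:
        return np.zeros(shape)
    return (noise - lo) / (hi - lo)


def _edge_distance_cells(forest: np.ndarray) -> np.ndarray:
    """Distance (in cells) from each forest cell to the nearest non-forest cell.

    The raster border counts as non-forest, matching the edge definition used
    by the accessibility stage.
    """
    padded = np.pad(forest, 1, constant_values=False)
    d = ndimage.distance_transform_edt(padded)
    return d[1:-1, 1:-1]


def _sample_without_replacement(
    rng: np.random.Generator, log_weights: np.ndarray, k: int
) -> np.ndarray:
    """Indices of a weighted sample without replacement (Gumbel top-k)."""
    gumbel = rng.gumbel(size=log_weights.size)
    keys = log_weights + gumbel
    return np.argpartition(-keys, k - 1)[:k]


def generate_landscape(config: SyntheticConfig) -> LandscapeStack:
    """Generate the full raster stack for a configuration.

    Realized t0 forest fraction is within ±0.05 of ``forest_fraction`` (it is
    hit by quantile thresholding, so usually much closer) and realized loss
    is exact up to integer rounding of the cleared-cell count.
    """
    grid = config.grid()
    rng = _rng_for(config, stream=0)
    extent_m = min(config.n_rows, config.n_cols) * config.cell_size

    # --- islands -----------------------------------------------------------
    margin = 0.18
    islands: List[Polygon] = []
    for _ in range(config.n_islands):
        cx = rng.uniform(margin, 1 - margin) * config.n_cols * config.cell_size
        cy = rng.uniform(margin, 1 - margin) * config.n_rows * config.cell_size
        radius = rng.uniform(*config.island_radius_range) * extent_m
        islands.append(_blob_polygon(rng, (cx, cy), radius))
    land = np.zeros(grid.shape, dtype=bool)
    for poly in islands:
        land |= rasterize_geometry(poly, grid)
    if not land.any():
        raise RuntimeError("island generation produced no land; enlarge radii")

    # --- elevation ---------------------------------------------------------
    rough = _smooth_noise(rng, grid.shape, sigma=max(2.0, extent_m / config.cell_size / 30))
    coast = ndimage.distance_transform_edt(land)
    coast = coast / coast.max() if coast.max() > 0 else coast
    elevation = config.relief * (0.35 * rough + 0.65 * np.sqrt(coast)) * land
    elevation = np.ascontiguousarray(elevation, dtype=np.float64)

    # --- forest at t0 (quantile thresholding hits the target fraction) -----
    n_land = int(np.count_nonzero(land))
    forest_t0 = np.zeros(grid.shape, dtype=bool)
    if config.forest_fraction > 0:
        score = _smooth_noise(rng, grid.shape, sigma=4.0)
        if config.forest_fraction >= 1.0:
            forest_t0 = land.copy()
        else:
            thresh = np.quantile(score[land], 1.0 - config.forest_fraction)
            forest_t0 = land & (score >= thresh)
            if not forest_t0.any():  # tiny grids: keep at least one cell
                forest_t0 = land & (score >= score[land].max())

    # --- edge-biased clearing ---------------------------------------------
    n_forest = int(np.count_nonzero(forest_t0))
    n_clear = int(round(config.loss_fraction * n_forest))
    forest_t1 = forest_t0.copy()
    if n_clear > 0:
        d_cells = _edge_distance_cells(forest_t0)
        rows, cols = np.nonzero(forest_t0)
        log_w = -config.edge_bias * d_cells[rows, cols]
        pick = _sample_without_replacement(rng, log_w, n_clear)
        forest_t1[rows[pick], cols[pick]] = False

    # --- two-country partition (by longitude quantile of land cells) -------
    country_a = np.zeros(grid.shape, dtype=bool)
    if config.country_a_fraction > 0 and n_land > 0:
        _, land_cols = np.nonzero(land)
        if config.country_a_fraction >= 1.0:
            country_a = land.copy()
        else:
            cut = np.quantile(land_cols, config.country_a_fraction)
            country_a = land & (np.arange(config.n_cols)[None, :] <= cut)

    # --- protected areas ---------------------------------------------------
    protected = np.zeros(grid.shape, dtype=bool)
    pa_polygons: List[Tuple[Polygon, str]] = []
    if config.pa_fraction > 0 and n_land > 0:
        land_rows, land_cols2 = np.nonzero(land)
        target = config.pa_fraction * n_land
        for _ in range(60):
            if np.count_nonzero(protected & land) >= target:
                break
            k = rng.integers(land_rows.size)
            cx = (land_cols2[k] + 0.5) * config.cell_size
            cy = (land_rows[k] + 0.5) * config.cell_size
            radius = rng.uniform(0.04, 0.10) * extent_m
            category = str(rng.choice(PA_CATEGORIES_ALL))
            poly = _blob_polygon(rng, (cx, cy), radius, roughness=0.25)
            pa_polygons.append((poly, category))
            if category in PA_CATEGORIES_KEPT:
                protected |= rasterize_geometry(poly, grid)

    # --- roads -------------------------------------------------------------
    roads = roads_major = None
    if config.with_roads:
        roads = np.zeros(grid.shape, dtype=bool)
        roads_major = np.zeros(grid.shape, dtype=bool)
        xmax = config.n_cols * config.cell_size
        ymax = config.n_rows * config.cell_size
        for r in range(config.n_roads):
            x0, y0 = rng.uniform(0, xmax), rng.uniform(0, ymax)
            angle = rng.uniform(0, np.pi)
            span = 2.0 * max(xmax, ymax)
            line = LineString(
                [
                    (x0 - span * np.cos(angle), y0 - span * np.sin(angle)),
                    (x0 + span * np.cos(angle), y0 + span * np.sin(angle)),
                ]
            )
            mask = rasterize_geometry(line.buffer(0.6 * config.cell_size), grid)
            roads |= mask
            if r < max(1, config.n_roads // 2):
                roads_major |= mask

    return LandscapeStack(
        grid=grid,
        forest_t0=forest_t0,
        forest_t1=forest_t1,
        elevation=elevation,
        country_a=country_a,
        protected=protected,
        land=land,
        roads=roads,
        roads_major=roads_major,
        years_between=config.years_between,
        island_polygons=islands,
        pa_polygons=pa_polygons,
    )


# ---------------------------------------------------------------------------
# Species generation
# ---------------------------------------------------------------------------


def generate_species(
    config: SyntheticConfig, landscape: LandscapeStack
) -> List[SpeciesRecord]:
    """Draw a seeded species set over a landscape.

    Each species gets a contiguous blob range centered on a land cell,
    optional elevation limits, an optional generation length, and a
    persecution category drawn from the configured distribution.
    """
    rng = _rng_for(config, stream=1)
    grid = landscape.grid
    extent_m = min(config.n_rows, config.n_cols) * config.cell_size
    land_rows, land_cols = np.nonzero(landscape.land)
    if land_rows.size == 0:
        raise RuntimeError("landscape has no land cells")

    species: List[SpeciesRecord] = []
    for i in range(config.n_species):
        k = rng.integers(land_rows.size)
        cx = (land_cols[k] + 0.5) * config.cell_size
        cy = (land_rows[k] + 0.5) * config.cell_size
        radius = rng.uniform(*config.range_radius_range) * extent_m
        geom = _blob_polygon(rng, (cx, cy), radius, roughness=0.3, n_vertices=48)

        elev_min = elev_max = None
        if rng.uniform() < config.elevation_limit_prob:
            elev_min = float(rng.uniform(0.0, 0.3 * config.relief))
            elev_max = float(elev_min + rng.uniform(0.3, 0.7) * config.relief)

        generation_length = None
        if rng.uniform() >= config.missing_generation_prob:
            generation_length = float(rng.uniform(*config.generation_length_range))

        persecution = str(
            rng.choice(PERSECUTION_LEVELS, p=config.persecution_probs)
        )
        species.append(
            SpeciesRecord(
                species_id=f"sp{i:03d}",
                range_geometry=geom,
                elev_min=elev_min,
                elev_max=elev_max,
                generation_length=generation_length,
                persecution=persecution,
            )
        )
    return species


# ---------------------------------------------------------------------------
# Vector / table export
# ---------------------------------------------------------------------------


def species_to_geojson(species: Sequence[SpeciesRecord]) -> Dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"species_id": sp.species_id},
                "geometry": shapely.geometry.mapping(sp.range_geometry),
            }
            for sp in species
        ],
    }


def pa_to_geojson(landscape: LandscapeStack) -> Dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"iucn_category": cat},
                "geometry": shapely.geometry.mapping(poly),
            }
            for poly, cat in landscape.pa_polygons
        ],
    }


def species_trait_table(species: Sequence[SpeciesRecord]):
    """Trait table as a pandas DataFrame (one row per species)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "species_id": sp.species_id,
                "elev_min": sp.elev_min,
                "elev_max": sp.elev_max,
                "generation_length": sp.generation_length,
                "persecution": sp.persecution,
                "forest_dependent": sp.forest_dependent,
            }
            for sp in species
        ]
    )


def config_to_dict(config: SyntheticConfig) -> Dict:
    return dataclasses.asdict(config)


def config_from_dict(raw: Dict) -> SyntheticConfig:
    kwargs = dict(raw)
    for key in ("island_radius_range", "range_radius_range", "generation_length_range", "persecution_probs"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return SyntheticConfig(**kwargs)
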