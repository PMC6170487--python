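"""End-to-end orchestration: simulate → habitat → access → exploit → redlist
→ protection → SAR, with reproducible per-stage outputs.

All randomness flows from the single seed in the run configuration; stage
outputs are written as CSV/JSON so any stage can be re-run or inspected in
isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accessibility import (
    DEFAULT_ACCESS_THRESHOLD_M,
    forest_edges,
    fraction_within,
    path_distance,
    road_sources,
)
from .exploitation import EfficacyModel, estimate_exploitation
from .grids import rasterize_geometry
from .habitat import SpeciesRecord, compute_esh, eoo_convex_hull, habitat_change
from .protection import protection_result
from .redlist import Thresholds, assess, summarize
from .sar import Z_LOWER, Z_UPPER, extinction_fraction, species_count
from .synthetic import (
    SyntheticConfig,
    config_from_dict,
    config_to_dict,
    generate_landscape,
    generate_species,
    pa_to_geojson,
    species_to_geojson,
    species_trait_table,
)

logger = logging.getLogger("deforisk")

__all__ = ["RunConfig", "AssessmentRun", "run_assessment", "load_run_config"]


@dataclass
class RunConfig:
    """Full pipeline configuration (synthetic inputs plus all thresholds)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    access_threshold_m: float = DEFAULT_ACCESS_THRESHOLD_M
    source_mode: str = "forest_edge"  # forest_edge | roads_major | roads_all
    thresholds: Thresholds = field(default_factory=Thresholds)
    efficacy: EfficacyModel = field(default_factory=EfficacyModel)
    observed_years: Optional[float] = None  # defaults to synthetic.years_between
    include_deforestation: bool = True
    include_exploitation: bool = True
    sar_z_values: tuple = (Z_LOWER, Z_UPPER)
    sar_horizon_years: float = 85.0
    eoo_nodata_fraction: float = 0.5
    raster_format: str = "asc"
    write_rasters: bool = True

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["efficacy"] = {
            cat: [p.minimum, p.mode, p.maximum, p.shape]
            for cat, p in self.efficacy.params.items()
        }
        return d


def load_run_config(path: str | Path) -> RunConfig:
    """Load a run configuration from YAML (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: Dict = {}
    if "synthetic" in raw:
        kwargs["synthetic"] = config_from_dict(raw["synthetic"])
    if "thresholds" in raw:
        kwargs["thresholds"] = Thresholds(**raw["thresholds"])
    if "efficacy" in raw:
        kwargs["efficacy"] = EfficacyModel.from_dict(raw["efficacy"])
    for key in (
        "access_threshold_m",
        "source_mode",
        "observed_years",
        "include_deforestation",
        "include_exploitation",
        "sar_horizon_years",
        "raster_format",
        "write_rasters",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "sar_z_values" in raw:
        kwargs["sar_z_values"] = tuple(raw["sar_z_values"])
    return RunConfig(**kwargs)


@dataclass
class AssessmentRun:
    """In-memory results of one full pipeline run."""

    config: RunConfig
    landscape: object
    species: List[SpeciesRecord]
    habitat_table: pd.DataFrame
    access_table: pd.DataFrame
    exploitation_table: pd.DataFrame
    assessment_table: pd.DataFrame
    protection_table: pd.DataFrame
    sar_table: pd.DataFrame
    summary: Dict


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_assessment(config: RunConfig, out_dir: Optional[str | Path] = None) -> AssessmentRun:
    """Run every stage on a synthetic landscape; optionally write outputs."""
    syn = config.synthetic
    observed_years = (
        config.observed_years if config.observed_years is not None else syn.years_between
    )

    logger.info("generating landscape (seed=%d)", syn.seed)
    landscape = generate_landscape(syn)
    species = generate_species(syn, landscape)
    grid = landscape.grid

    # --- habitat stage -----------------------------------------------------
    range_masks = {
        sp.species_id: rasterize_geometry(sp.range_geometry, grid) for sp in species
    }
    esh_t0, esh_t1, changes = {}, {}, {}
    habitat_rows = []
    for sp in species:
        rm = range_masks[sp.species_id]
        e0 = compute_esh(sp, landscape.forest_t0, landscape.elevation, grid, "t0", rm)
        e1 = compute_esh(sp, landscape.forest_t1, landscape.elevation, grid, "t1", rm)
        if not config.include_deforestation:
            # ablation: freeze habitat at t0 so deforestation contributes 0
            e1 = e0
        esh_t0[sp.species_id], esh_t1[sp.species_id] = e0, e1
        ch = habitat_change(e0, e1)
        changes[sp.species_id] = ch
        habitat_rows.append(
            {
                "species_id": sp.species_id,
                "area_t0_km2": ch.area_t0_km2,
                "area_t1_km2": ch.area_t1_km2,
                "p_loss": ch.p_loss,
                "increase": ch.increase,
                "undefined": ch.undefined,
            }
        )
    habitat_table = pd.DataFrame(habitat_rows)

    # --- accessibility stage ----------------------------------------------
    if config.source_mode == "forest_edge":
        sources = forest_edges(landscape.forest_t1)
    else:
        sources = road_sources(
            landscape.roads,
            landscape.forest_t1,
            landscape.roads_major,
            major_only=config.source_mode == "roads_major",
        )
    dist = path_distance(landscape.forest_t1, landscape.elevation, sources, grid)

    access_rows, estimates = [], {}
    for sp in species:
        e1 = esh_t1[sp.species_id]
        acc = fraction_within(e1, dist, config.access_threshold_m)
        n_esh = int(np.count_nonzero(e1.mask))
        p_country = (
            float(np.count_nonzero(e1.mask & landscape.country_a)) / n_esh
            if n_esh
            else float("nan")
        )
        access_rows.append(
            {
                "species_id": sp.species_id,
                "threshold_m": config.access_threshold_m,
                "fraction_within": acc.fraction_within,
                "p_country": p_country,
                "source_mode": config.source_mode,
            }
        )
        category = sp.persecution if config.include_exploitation else "none"
        if category != "none" and n_esh > 0:
            estimates[sp.species_id] = estimate_exploitation(
                sp.species_id, category, p_country, acc.fraction_within, config.efficacy
            )
    access_table = pd.DataFrame(access_rows)
    exploitation_table = pd.DataFrame(
        [dataclasses.asdict(est) for est in estimates.values()]
    )

    # --- EOO + endemism ----------------------------------------------------
    region_fraction, eoo = {}, {}
    for sp in species:
        rm = range_masks[sp.species_id]
        n_range = int(np.count_nonzero(rm))
        region_fraction[sp.species_id] = (
            float(np.count_nonzero(rm & landscape.land)) / n_range if n_range else 0.0
        )
        e1 = esh_t1[sp.species_id]
        if e1.mask.any():
            eoo[sp.species_id] = eoo_convex_hull(e1.mask, grid)
        elif n_range:
            # no suitable habitat left on the map: fall back to the range hull
            eoo[sp.species_id] = eoo_convex_hull(rm, grid)

    # --- red list stage ----------------------------------------------------
    assessments = assess(
        species,
        changes,
        estimates,
        region_fraction,
        eoo,
        observed_years=observed_years,
        thresholds=config.thresholds,
    )
    assessment_table = pd.DataFrame(
        [
            {**dataclasses.asdict(a), "flags": ";".join(a.flags)}
            for a in assessments
        ]
    )
    summary = summarize(assessments)

    # --- protection stage --------------------------------------------------
    protection_rows = []
    for sp in species:
        pr = protection_result(
            esh_t1[sp.species_id],
            landscape.protected,
            dist,
            grid,
            threshold_m=config.access_threshold_m,
        )
        protection_rows.append(dataclasses.asdict(pr))
    protection_table = pd.DataFrame(protection_rows)

    # --- SAR stage ---------------------------------------------------------
    n_forest_t0 = int(np.count_nonzero(landscape.forest_t0))
    n_forest_t1 = int(np.count_nonzero(landscape.forest_t1))
    annual_rate = (
        (1.0 - (n_forest_t1 / n_forest_t0) ** (1.0 / syn.years_between))
        if n_forest_t0
        else 0.0
    )
    ratio_horizon = (1.0 - annual_rate) ** config.sar_horizon_years
    sar_rows = []
    for z in config.sar_z_values:
        frac = extinction_fraction(ratio_horizon, z)
        sar_rows.append(
            {
                "z": z,
                "annual_rate": annual_rate,
                "habitat_ratio_horizon": ratio_horizon,
                "extinction_fraction": frac,
                "extinct_species": species_count(frac, len(species)),
            }
        )
    sar_table = pd.DataFrame(sar_rows)

    summary = {
        "n_species": len(species),
        "seed": syn.seed,
        "source_mode": config.source_mode,
        **summary,
        "sar": sar_rows,
    }

    run = AssessmentRun(
        config,
        landscape,
        species,
        habitat_table,
        access_table,
        exploitation_table,
        assessment_table,
        protection_table,
        sar_table,
        summary,
    )
    if out_dir is not None:
        _write_outputs(run, Path(out_dir))
    return run


def _write_outputs(run: AssessmentRun, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = run.config
    if cfg.write_rasters:
        run.landscape.write(out_dir / "layers", fmt=cfg.raster_format)
    with open(out_dir / "species.geojson", "w") as fh:
        json.dump(species_to_geojson(run.species), fh)
    with open(out_dir / "protected_areas.geojson", "w") as fh:
        json.dump(pa_to_geojson(run.landscape), fh)
    species_trait_table(run.species).to_csv(out_dir / "species_traits.csv", index=False)
    run.habitat_table.to_csv(out_dir / "habitat_change.csv", index=False)
    run.access_table.to_csv(out_dir / "access.csv", index=False)
    run.exploitation_table.to_csv(out_dir / "exploitation.csv", index=False)
    run.assessment_table.to_csv(out_dir / "assessment.csv", index=False)
    run.protection_table.to_csv(out_dir / "protection.csv", index=False)
    run.sar_table.to_csv(out_dir / "sar.csv", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(run.summary, fh, indent=2, sort_keys=True)
    provenance = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.synthetic.seed,
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
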