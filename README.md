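# deforisk

Combined deforestation + wildlife-exploitation threat assessment on raster
landscapes: from forest/elevation rasters and species range polygons to
per-species population-decline estimates with uncertainty, Red List
categories, species-area extinction projections, and protected-area
core-coverage statistics. Ships a seeded synthetic-landscape generator so
the whole pipeline is testable end-to-end without any external data.

## Pipeline stages

1. **synthetic** — multi-island equal-area landscapes (forest at two dates
   with edge-biased clearing, elevation, a two-country partition, protected
   areas, optional roads) plus species ranges and traits, all from one seed.
2. **habitat** — extent of suitable habitat (range ∧ forest ∧ elevation
   band), habitat change, convex-hull extent of occurrence.
3. **accessibility** — elevation-aware path distance from forest edges (or
   roads) through forest; fraction of habitat within a trapper-penetration
   threshold (default 5 km).
4. **exploitation** — Beta-PERT efficacy distributions per persecution
   category; decline = P (country fraction) × E (accessible fraction) × H
   (efficacy), with a 95% interval from the 2.5/97.5 efficacy percentiles.
5. **redlist** — proportional-decay decline projection over
   max(3 generations, 10 years), additive combination of the two threats,
   decline and EOO categorization, endemism filtering, summary aggregation.
6. **protection** — protected-area coverage of habitat and of the
   hunting-safe core (beyond the penetration threshold from the edge).
7. **sar** — species-area relationship extinction fractions
   (`1 − ratio^z`), inversion, and constant-rate forest projection.

## CLI

```bash
deforisk run-all --seed 1 --out-dir scratch/run1       # full pipeline
deforisk simulate --seed 1 --out-dir scratch/sim1      # just the inputs
deforisk habitat --run-dir scratch/sim1                # per-stage re-runs
deforisk access --run-dir scratch/sim1 --threshold-m 7000
deforisk exploit --run-dir scratch/sim1
deforisk redlist --run-dir scratch/sim1
deforisk protect --run-dir scratch/sim1
deforisk sar --extinction-fraction 0.169 --known-z 0.18 --pool 308
```

`run-all` writes per-stage CSVs, `summary.json` (category counts, driver
attribution, mean declines), and `provenance.json` (config hash, seed,
version). Identical config + seed produces byte-identical summaries. A YAML
config (`--config`) can override every threshold, the efficacy parameters,
the access source mode (`forest_edge`, `roads_major`, `roads_all`), and the
synthetic-landscape knobs.

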