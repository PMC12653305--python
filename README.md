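# zndvi

A tested, reusable pipeline for satellite-based forest-health anomaly
monitoring: cloud-masked growing-season composites → NDVI → per-pixel
standardized anomaly (Z NDVI) → five damage classes → plot-level
extraction → agreement statistics against field defoliation, plus a
temperature–precipitation drought factor (TPF) and its regression
against plot anomalies.  A first-class synthetic-scene generator
produces Sentinel-2-like multi-year raster stacks, plot networks,
defoliation responses and climate series with known ground truth, so
every stage is testable end-to-end without external data.

## Layout

| module | what it does |
| --- | --- |
| `zndvi.synthetic` | multi-year scene stacks, plot networks, climate series with injected disturbances and one-seed determinism |
| `zndvi.preprocess` | scene prefilter (metadata cloud % ≤ 5, April–October season), per-pixel QA-bit/scene-class masking, per-band median composites |
| `zndvi.indices` | NDVI, standardized anomaly (z over a multi-year baseline), five-class damage maps, class-distribution tables |
| `zndvi.plots` | window-mean extraction of z around monitoring plots, plots-per-class yearly tables |
| `zndvi.climate` | TPF = 100 × mean T / total P over March–August; OLS regression of plot anomalies on TPF |
| `zndvi.validation` | defoliation categories, damaged/healthy binarization, confusion metrics, Cohen's kappa, R²/RMSE, pooled per-stratum reports |
| `zndvi.pipeline` / `zndvi.cli` | orchestration, clipping, JSON run manifest with checksums, `zndvi` CLI |
| `zndvi.raster_io` | multiband TIFF + JSON-manifest I/O (band names, transform and tags in the image description) |
| `zndvi.figures` | optional stacked-bar and heatmap figures (`pip install zndvi[plot]`) |

## CLI

All-in-one demo run (simulates a 7-year 20×20 scene stack with a 2022
drought disturbance, then runs every stage):

```bash
zndvi run --demo --seed 1 --out scratch/demo
zndvi report --run-dir scratch/demo
```

Stage-by-stage:

```bash
zndvi simulate --seed 1 --out scratch/sim
zndvi composite --manifest scratch/sim/manifest.json --out scratch/comp
zndvi zndvi scratch/comp/composite_*.tif --out scratch/z
zndvi classify scratch/z/z_*.tif --out scratch/cls
zndvi extract --z-dir scratch/z --plots scratch/sim/plots.csv --out scratch/series.csv
zndvi climate --climate scratch/sim/climate.csv --out scratch/tpf.csv
zndvi validate --series scratch/series.csv --plots scratch/sim/plots.csv --out scratch/agree.csv
```

Key conventions (all configurable):
- scene prefilter keeps `cloud_pct <= 5` (strictly-more-than-5 excluded);
- QA bit presets `"paper"` = {9, 10, 11} (default) and `"qa60-standard"` =
  {10, 11}; excluded scene classes {3, 7, 8, 9};
- baseline statistics use the population SD (`ddof=0`) over all years,
  including the evaluated year; `ddof=1` available;
- class bins are lower-inclusive half-open: (−∞,−2) severe damage,
  [−2,−1) damage, [−1,0) moderate, [0,1) regeneration, [1,∞) strong
  regeneration;
- plot extraction uses a 3×3 pixel window mean by default (mode
  aggregation behind a flag);
- binarization defaults: satellite positive ⇔ class ∈ {severe damage,
  damage}; field positive ⇔ defoliation > 25% (Medium/Severe/Dead); the
  rule is serialized into every agreement report.

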