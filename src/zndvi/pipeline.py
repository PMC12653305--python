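"""End-to-end orchestration: simulate/load -> mask -> composite -> NDVI
-> anomaly -> classes -> plot extraction -> climate -> agreement, with a
JSON run manifest recording config, checksums and per-stage counts."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from zndvi import climate as climate_mod
from zndvi import raster_io
from zndvi.indices import CLASS_NAMES, class_distribution, ndvi, z_ndvi
from zndvi.plots import extract_plot_z, level_table, read_plot_csv, records_to_frame
from zndvi.preprocess import MaskConfig, mask_pixels, median_composite, prefilter_scenes
from zndvi.synthetic import SimulationConfig, simulate_climate, simulate_plots, simulate_scenes
from zndvi.validation import BinarizationRule, join_series_records, pooled_report

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path
    scene_manifest: Path | None = None
    plot_csv: Path | None = None
    climate_csv: Path | None = None
    simulate: SimulationConfig | None = None
    mask: MaskConfig = field(default_factory=MaskConfig)
    baseline_years: tuple[int, ...] | None = None
    sd_ddof: int = 0
    window: int = 1
    aggregate: str = "mean"
    rule: BinarizationRule = field(default_factory=BinarizationRule)
    per_scene_ndvi: bool = False
    clip_mask: Path | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        def enc(v):
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, frozenset):
                return sorted(v)
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(getattr(v, k)) for k in v.__dataclass_fields__}
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (tuple, list)):
                return [enc(i) for i in v]
            return v

        return {k: enc(getattr(self, k)) for k in self.__dataclass_fields__}


def clip_to_mask(grid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Invalidate (NaN) pixels outside a boolean clip mask."""
    grid = np.asarray(grid, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(
            f"clip mask extent {mask.shape} does not match grid {grid.shape}"
        )
    if not mask.any():
        log.warning("clip mask is empty: all pixels invalidated")
    return np.where(mask, grid, np.nan)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_error(stage: str, exc: Exception) -> RuntimeError:
    return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to
    ``<out_dir>/run_manifest.json``).

    Without a plot table the pipeline stops cleanly after the class
    distributions; without a climate table the TPF stage is skipped.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, object] = {}

    # --- inputs -----------------------------------------------------
    if cfg.simulate is not None:
        sim = cfg.simulate
        scenes_by_year, truth = simulate_scenes(sim)
        records = simulate_plots(sim, truth)
        climates = simulate_climate(sim)
        manifest_path = raster_io.write_scene_set(
            out / "input", scenes_by_year, pixel_size=sim.pixel_size
        )
        plot_csv = out / "input" / "plots.csv"
        records_to_frame(records).to_csv(plot_csv, index=False)
        clim_csv = out / "input" / "climate.csv"
        pd.concat([c.data for c in climates.values()]).to_csv(clim_csv, index=False)
        outputs["scene_manifest"] = manifest_path
        outputs["plot_csv"] = plot_csv
        outputs["climate_csv"] = clim_csv
    else:
        if cfg.scene_manifest is None:
            raise _stage_error("inputs", ValueError("no scene manifest and no simulation config"))
        scenes_by_year = raster_io.read_scene_set(cfg.scene_manifest)
        records = read_plot_csv(cfg.plot_csv) if cfg.plot_csv else None
        climates = (
            climate_mod.read_climate_csv(cfg.climate_csv) if cfg.climate_csv else None
        )
    counts["n_years"] = len(scenes_by_year)
    counts["n_scenes"] = sum(len(v) for v in scenes_by_year.values())

    # --- mask + composite -------------------------------------------
    composites = {}
    kept_counts = {}
    for year in sorted(scenes_by_year):
        try:
            kept = prefilter_scenes(scenes_by_year[year], cfg.mask)
            kept_counts[year] = len(kept)
            if not kept:
                log.warning("year %s: no scenes survive prefiltering", year)
                continue
            masked = [mask_pixels(s, cfg.mask) for s in kept]
            comp = median_composite(masked, year, per_scene_ndvi=cfg.per_scene_ndvi)
        except Exception as exc:  # pragma: no cover - defensive
            raise _stage_error(f"composite[{year}]", exc)
        composites[year] = comp
        outputs[f"composite_{year}"] = raster_io.write_composite(
            out / f"composite_{year}.tif", comp,
            tags={"mask": cfg.mask.__dict__ | {"qa_cloud_bits": sorted(cfg.mask.qa_cloud_bits),
                                               "scl_excluded": sorted(cfg.mask.scl_excluded)}},
        )
    counts["scenes_kept"] = kept_counts
    if not composites:
        raise _stage_error("composite", ValueError("no year produced a composite"))

    # --- NDVI + anomaly + classes -----------------------------------
    clip = None
    if cfg.clip_mask is not None:
        bands, _ = raster_io.read_grids(cfg.clip_mask)
        clip = next(iter(bands.values())).astype(bool)
    ndvi_by_year = {}
    for year, comp in composites.items():
        grid = comp.ndvi if comp.ndvi is not None else ndvi(comp.red, comp.nir)
        grid = np.where(comp.valid_mask, grid, np.nan)
        if clip is not None:
            grid = clip_to_mask(grid, clip)
        ndvi_by_year[year] = grid
    baseline = cfg.baseline_years or tuple(sorted(ndvi_by_year))
    anoms = z_ndvi(ndvi_by_year, baseline_years=baseline, ddof=cfg.sd_ddof).classify_all()
    counts["n_degenerate_pixels"] = anoms.n_degenerate

    dist_frames = []
    for year in anoms.years:
        outputs[f"z_{year}"] = raster_io.write_grids(
            out / f"z_{year}.tif", [anoms.z[year]], ["Z_NDVI"],
            tags={"year": year, "sd_ddof": cfg.sd_ddof, "baseline_years": list(baseline)},
        )
        outputs[f"classes_{year}"] = raster_io.write_grids(
            out / f"classes_{year}.tif", [anoms.classes[year].astype(float)], ["CLASS"],
            tags={"year": year, "class_names": list(CLASS_NAMES)},
        )
        dist_frames.append(class_distribution(anoms.classes[year], year).to_frame())
    dist_csv = out / "class_distribution.csv"
    pd.concat(dist_frames).to_csv(dist_csv, index=False)
    outputs["class_distribution"] = dist_csv

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "counts": counts,
    }

    # --- plots -------------------------------------------------------
    if records is None:
        log.warning("no plot table supplied: stopping after class distribution")
        return _finish(out, manifest, outputs)
    series = extract_plot_z(anoms, records, window=cfg.window, aggregate=cfg.aggregate)
    series_rows = [
        {"plot_id": s.plot_id, "level": s.level, "year": y,
         "z_mean": s.z_mean[y], "class": s.cls[y], "n_valid": s.n_valid[y]}
        for s in series
        for y in anoms.years
    ]
    series_csv = out / "plot_series.csv"
    pd.DataFrame(series_rows).to_csv(series_csv, index=False)
    outputs["plot_series"] = series_csv
    for lvl in ("I", "II"):
        sub = [s for s in series if s.level == lvl]
        if sub:
            path = out / f"level_{lvl}_class_counts.csv"
            level_table(sub).to_csv(path)
            outputs[f"level_{lvl}_table"] = path
    counts["n_plots"] = len(series)

    # --- climate -----------------------------------------------------
    if climates:
        tpf_rows = []
        for site_id, cs in sorted(climates.items()):
            for year in cs.years:
                tpf_rows.append(
                    {"site_id": site_id, "year": year,
                     "tpf": climate_mod.tpf(cs, year)}
                )
        tpf_df = pd.DataFrame(tpf_rows)
        tpf_csv = out / "tpf.csv"
        tpf_df.to_csv(tpf_csv, index=False)
        outputs["tpf"] = tpf_csv

        by_plot = {s.plot_id: s for s in series}
        reg_rows = []
        for site_id, cs in sorted(climates.items()):
            tpf_by_year = {r["year"]: r["tpf"] for r in tpf_rows if r["site_id"] == site_id}
            s = by_plot.get(site_id)
            if s is None:
                continue
            try:
                res = climate_mod.fit_tpf_vs_z(tpf_by_year, s.z_mean)
            except ValueError as exc:
                log.info("tpf regression skipped for %s: %s", site_id, exc)
                continue
            reg_rows.append({"site_id": site_id, **dataclasses.asdict(res)})
        if reg_rows:
            reg_csv = out / "tpf_regression.csv"
            pd.DataFrame(reg_rows).to_csv(reg_csv, index=False)
            outputs["tpf_regression"] = reg_csv

    # --- agreement ---------------------------------------------------
    joined = join_series_records(series, records)
    for strata in ("year", "plot", "level"):
        reports = pooled_report(joined, strata=strata, rule=cfg.rule)
        df = pd.DataFrame([r.to_row() for r in reports]).round(2)
        df["rule"] = json.dumps(cfg.rule.to_dict())
        path = out / f"agreement_by_{strata}.csv"
        df.to_csv(path, index=False)
        outputs[f"agreement_by_{strata}"] = path
    counts["n_pairs"] = len(joined)

    return _finish(out, manifest, outputs)


def _finish(out: Path, manifest: dict, outputs: dict[str, Path]) -> dict:
    manifest["outputs"] = {
        k: {"path": str(Path(p).relative_to(out)), "sha256": _sha256(p)}
        for k, p in sorted(outputs.items())
    }
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(path)
    return manifest
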