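"""TIFF + CSV + JSON-manifest I/O for scenes, composites and grids.

Rasters are written as multiband TIFFs with a JSON blob in the image
description carrying band names, the affine geotransform, the
acquisition date and arbitrary processing tags.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from zndvi.preprocess import AnnualComposite, SceneStack

SCENE_BANDS = ("RED", "NIR", "QA", "SCL")


def _default_transform(pixel_size: float) -> list[float]:
    # north-up affine: (x0, dx, 0, y0, 0, -dy)
    return [0.0, pixel_size, 0.0, 0.0, 0.0, -pixel_size]


def write_grids(
    path: Path,
    grids: Sequence[np.ndarray],
    band_names: Sequence[str],
    tags: Mapping | None = None,
    pixel_size: float = 10.0,
) -> Path:
    """Stack 2-D grids into one multiband float64 TIFF with metadata."""
    path = Path(path)
    stack = np.stack([np.asarray(g, dtype=np.float64) for g in grids])
    meta = {
        "bands": list(band_names),
        "transform": _default_transform(pixel_size),
        "tags": dict(tags or {}),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack, description=json.dumps(meta),
                     photometric="minisblack")
    return path


def read_grids(path: Path) -> tuple[dict[str, np.ndarray], dict]:
    """Inverse of :func:`write_grids`: band-name -> grid plus metadata."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description or "{}"
    meta = json.loads(desc)
    names = meta.get("bands", [f"band{i}" for i in range(stack.shape[0])])
    if stack.ndim == 2:
        stack = stack[None]
    return {n: stack[i] for i, n in enumerate(names)}, meta


def write_scene(path: Path, scene: SceneStack, pixel_size: float = 10.0) -> Path:
    return write_grids(
        path,
        [scene.red, scene.nir, scene.qa_bits.astype(float), scene.scene_class.astype(float)],
        SCENE_BANDS,
        tags={"date": scene.date.isoformat(), "cloud_pct": scene.cloud_pct},
        pixel_size=pixel_size,
    )


def read_scene(path: Path) -> SceneStack:
    bands, meta = read_grids(path)
    tags = meta.get("tags", {})
    return SceneStack(
        red=bands["RED"],
        nir=bands["NIR"],
        qa_bits=bands["QA"].astype(np.uint16),
        scene_class=bands["SCL"].astype(np.uint8),
        date=dt.date.fromisoformat(tags["date"]),
        cloud_pct=float(tags["cloud_pct"]),
    )


def write_scene_set(
    out_dir: Path,
    scenes_by_year: Mapping[int, Sequence[SceneStack]],
    pixel_size: float = 10.0,
) -> Path:
    """Write all scenes plus a manifest listing path/date/cloud_pct."""
    out_dir = Path(out_dir)
    entries = []
    for year, scenes in scenes_by_year.items():
        for i, scene in enumerate(scenes):
            rel = f"scenes/{year}/scene_{i:02d}.tif"
            write_scene(out_dir / rel, scene, pixel_size)
            entries.append(
                {
                    "path": rel,
                    "year": int(year),
                    "date": scene.date.isoformat(),
                    "cloud_pct": scene.cloud_pct,
                }
            )
    manifest = {"pixel_size": pixel_size, "scenes": entries}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_scene_set(manifest_path: Path) -> dict[int, list[SceneStack]]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    out: dict[int, list[SceneStack]] = {}
    for entry in manifest["scenes"]:
        out.setdefault(int(entry["year"]), []).append(read_scene(root / entry["path"]))
    return out


def write_composite(path: Path, comp: AnnualComposite, tags: Mapping | None = None,
                    pixel_size: float = 10.0) -> Path:
    grids = [comp.red, comp.nir, comp.n_obs.astype(float), comp.valid_mask.astype(float)]
    names = ["RED", "NIR", "N_OBS", "VALID"]
    if comp.ndvi is not None:
        grids.append(comp.ndvi)
        names.append("NDVI")
    all_tags = {"year": int(comp.year), **(tags or {})}
    return write_grids(path, grids, names, tags=all_tags, pixel_size=pixel_size)


def read_composite(path: Path) -> AnnualComposite:
    bands, meta = read_grids(path)
    return AnnualComposite(
        year=int(meta["tags"]["year"]),
        red=bands["RED"],
        nir=bands["NIR"],
        n_obs=bands["N_OBS"].astype(np.int32),
        valid_mask=bands["VALID"].astype(bool),
        ndvi=bands.get("NDVI"),
    )
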