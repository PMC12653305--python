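"""Scene prefiltering, per-pixel quality masking, and growing-season median composites.

The cloud screening is three-staged: (1) drop whole scenes whose metadata
cloud percentage exceeds a threshold or whose date falls outside the
growing season; (2) mask individual pixels using a quality bitmask and a
scene-classification band; (3) reduce the surviving observations to one
per-band median image per year.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

#: Named quality-bit presets.  "paper" follows the bit list used by the
#: source method; "qa60-standard" keeps only the two bits the standard
#: Sentinel-2 QA60 layout actually defines (10 opaque cloud, 11 cirrus).
QA_BIT_PRESETS: dict[str, frozenset[int]] = {
    "paper": frozenset({9, 10, 11}),
    "qa60-standard": frozenset({10, 11}),
}

#: Scene-classification codes excluded by default: 3 cloud shadow,
#: 7/8/9 cloud-probability classes.
DEFAULT_SCL_EXCLUDED: frozenset[int] = frozenset({3, 7, 8, 9})


@dataclass(eq=False)
class SceneStack:
    """One acquisition: reflectance bands, quality bands, and metadata.

    Attributes
    ----------
    red, nir : float arrays, surface reflectance.
    qa_bits : integer bitmask grid (cloud/cirrus flag bits).
    scene_class : integer scene-classification grid.
    date : acquisition date.
    cloud_pct : metadata percent of the scene flagged cloudy, in [0, 100].
    valid : optional boolean grid set by :func:`mask_pixels`; ``None``
        means no per-pixel screening has been applied yet.
    """

    red: np.ndarray
    nir: np.ndarray
    qa_bits: np.ndarray
    scene_class: np.ndarray
    date: dt.date
    cloud_pct: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {
            np.asarray(g).shape
            for g in (self.red, self.nir, self.qa_bits, self.scene_class)
        }
        if len(shapes) != 1:
            raise ValueError(f"scene bands have mismatched shapes: {shapes}")
        if not 0.0 <= self.cloud_pct <= 100.0:
            raise ValueError(f"cloud_pct must be in [0, 100], got {self.cloud_pct}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass(frozen=True)
class MaskConfig:
    """Parameters of the three-stage cloud screening.

    ``max_cloud_pct`` is the scene prefilter threshold: scenes with
    *more* than this metadata cloud percentage are dropped (boundary
    kept).  ``qa_cloud_bits`` and ``scl_excluded`` drive per-pixel
    masking.  The season window is inclusive on both ends and compared
    within each scene's own calendar year.
    """

    max_cloud_pct: float = 5.0
    qa_cloud_bits: frozenset[int] = QA_BIT_PRESETS["paper"]
    scl_excluded: frozenset[int] = DEFAULT_SCL_EXCLUDED
    season_start: tuple[int, int] = (4, 1)  # (month, day)
    season_end: tuple[int, int] = (10, 31)

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_cloud_pct <= 100.0:
            raise ValueError("max_cloud_pct must be in [0, 100]")
        if any(b < 0 or b >= 16 for b in self.qa_cloud_bits):
            raise ValueError("QA bit indices must be in [0, 16)")

    @classmethod
    def with_preset(cls, preset: str, **kwargs) -> "MaskConfig":
        bits = QA_BIT_PRESETS[preset]
        log.info("mask: using QA bit preset %r -> bits %s", preset, sorted(bits))
        return cls(qa_cloud_bits=bits, **kwargs)

    @property
    def qa_mask_word(self) -> int:
        word = 0
        for b in self.qa_cloud_bits:
            word |= 1 << b
        return word


@dataclass
class AnnualComposite:
    """Per-band median over all valid observations of one growing season."""

    year: int
    red: np.ndarray
    nir: np.ndarray
    n_obs: np.ndarray
    valid_mask: np.ndarray
    ndvi: np.ndarray | None = None  # filled when compositing per-scene NDVI

    def __post_init__(self) -> None:
        if bool(np.any(self.valid_mask != (self.n_obs > 0))):
            raise ValueError("valid_mask must equal (n_obs > 0)")


def _in_season(date: dt.date, cfg: MaskConfig) -> bool:
    start = dt.date(date.year, *cfg.season_start)
    end = dt.date(date.year, *cfg.season_end)
    return start <= date <= end


def prefilter_scenes(
    scenes: Sequence[SceneStack], cfg: MaskConfig | None = None
) -> list[SceneStack]:
    """Keep scenes with metadata cloud percentage <= threshold and an
    in-season date; order preserved.  An empty result is allowed but
    logged as a warning.
    """
    cfg = cfg or MaskConfig()
    if len(scenes) == 0:
        raise ValueError("prefilter_scenes requires at least one scene")
    kept = [
        s
        for s in scenes
        if s.cloud_pct <= cfg.max_cloud_pct and _in_season(s.date, cfg)
    ]
    dropped = len(scenes) - len(kept)
    if dropped:
        log.info("prefilter: dropped %d of %d scenes", dropped, len(scenes))
    if not kept:
        log.warning("prefilter: no scenes survived (of %d)", len(scenes))
    return kept


def mask_pixels(scene: SceneStack, cfg: MaskConfig | None = None) -> SceneStack:
    """Flag per-pixel validity: a pixel is invalid iff any configured QA
    bit is set or its scene-classification code is excluded.  Reflectance
    is left untouched; masking is idempotent.
    """
    cfg = cfg or MaskConfig()
    if scene.qa_bits is None:
        raise ValueError("scene is missing the quality bitmask band (qa_bits)")
    if scene.scene_class is None:
        raise ValueError("scene is missing the scene-classification band (scene_class)")
    qa_bad = (scene.qa_bits.astype(np.int64) & cfg.qa_mask_word) != 0
    scl_bad = np.isin(scene.scene_class, list(cfg.scl_excluded))
    valid = ~(qa_bad | scl_bad)
    if scene.valid is not None:
        valid &= scene.valid
    return replace(scene, valid=valid)


def median_composite(
    scenes: Sequence[SceneStack],
    year: int,
    per_scene_ndvi: bool = False,
) -> AnnualComposite:
    """Per-pixel, per-band median over valid observations.

    Even observation counts take the arithmetic mean of the two central
    values.  Pixels with zero valid observations are marked invalid
    rather than raising.  With ``per_scene_ndvi=True`` the NDVI is
    computed per scene first and the median taken over NDVI values (a
    sensitivity-check mode); the default composites reflectance bands
    and leaves NDVI to the indices stage.
    """
    if len(scenes) == 0:
        raise ValueError(f"median_composite: no scenes for year {year}")
    shape = scenes[0].shape
    n = len(scenes)
    red = np.full((n, *shape), np.nan)
    nir = np.full((n, *shape), np.nan)
    for i, s in enumerate(scenes):
        if s.shape != shape:
            raise ValueError("scenes have mismatched shapes")
        v = s.valid if s.valid is not None else np.ones(shape, dtype=bool)
        red[i][v] = np.asarray(s.red, dtype=float)[v]
        nir[i][v] = np.asarray(s.nir, dtype=float)[v]
    n_obs = np.sum(~np.isnan(red), axis=0).astype(np.int32)
    valid_mask = n_obs > 0
    with np.errstate(all="ignore"):
        red_med = np.nanmedian(red, axis=0)
        nir_med = np.nanmedian(nir, axis=0)
        ndvi_med = None
        if per_scene_ndvi:
            denom = nir + red
            nv = np.where(denom != 0, (nir - red) / np.where(denom == 0, 1, denom), np.nan)
            ndvi_med = np.nanmedian(nv, axis=0)
    red_med[~valid_mask] = np.nan
    nir_med[~valid_mask] = np.nan
    if ndvi_med is not None:
        ndvi_med[~valid_mask] = np.nan
    return AnnualComposite(
        year=year, red=red_med, nir=nir_med, n_obs=n_obs,
        valid_mask=valid_mask, ndvi=ndvi_med,
    )
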