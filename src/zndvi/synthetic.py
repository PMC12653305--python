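"""Synthetic multi-year scene stacks, plot networks and climate series.

Everything derives from one seed through a fixed stream-splitting order
(scenes -> clouds -> plots -> climate), so identical configurations give
bit-identical output and each downstream stage can be checked against
the known ground truth.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from zndvi.preprocess import SceneStack
from zndvi.validation import categorize_defoliation

__all__ = [
    "DisturbanceEvent",
    "SimulationConfig",
    "GroundTruth",
    "simulate_scenes",
    "simulate_plots",
    "simulate_climate",
]

# QA / scene-class codes used for simulated contamination.  Each cloudy
# block is stamped with one of these so every masking path is exercised.
_QA_OPAQUE = 1 << 10
_QA_CIRRUS = 1 << 11
_SCL_SHADOW = 3
_SCL_CLOUD_MED = 8
_SCL_CLOUD_HIGH = 9
_SCL_VEGETATION = 4

# Day-of-year anchors for acquisitions: evenly spread over April-October.
_SEASON_START_DOY = 105  # ~April 15
_SEASON_END_DOY = 288  # ~October 15


@dataclass(frozen=True)
class DisturbanceEvent:
    """One injected canopy disturbance.

    ``footprint`` is either a fraction in (0, 1] (the first
    ``round(fraction * n_pixels)`` pixels in row-major order) or an
    explicit boolean mask of the full grid.  ``ndvi_drop`` is subtracted
    from the true NDVI inside the footprint for that year.
    """

    year: int
    footprint: float | np.ndarray
    ndvi_drop: float

    def resolve(self, shape: tuple[int, int]) -> np.ndarray:
        if isinstance(self.footprint, np.ndarray):
            mask = np.asarray(self.footprint, dtype=bool)
            if mask.shape != shape:
                raise ValueError(
                    f"disturbance footprint shape {mask.shape} does not match "
                    f"grid {shape}"
                )
            return mask
        frac = float(self.footprint)
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"footprint fraction must be in (0, 1], got {frac}")
        n = shape[0] * shape[1]
        k = int(round(frac * n))
        flat = np.zeros(n, dtype=bool)
        flat[:k] = True
        return flat.reshape(shape)


@dataclass(frozen=True)
class SimulationConfig:
    years: tuple[int, ...] = (2017, 2018, 2019, 2020, 2021, 2022, 2023)
    grid_rows: int = 20
    grid_cols: int = 20
    pixel_size: float = 10.0
    scenes_per_year: int = 8
    baseline_ndvi: float = 0.8
    interannual_sd: float = 0.02
    year_effects: tuple[float, ...] | None = None  # explicit per-year offsets
    disturbance_events: tuple[DisturbanceEvent, ...] = ()
    cloud_fraction: float = 0.0
    cloud_block: int = 4
    n_plots_level1: int = 78
    n_plots_level2: int = 7
    defoliation_base: float = 5.0
    defoliation_gain: float = 100.0
    noise_sd: float = 0.0
    defol_noise_sd: float | None = None  # defaults to noise_sd scaled to %
    drought_coupling: bool = True
    drought_precip_factor: float = 0.6
    drought_temp_offset: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_ndvi < 1.0:
            raise ValueError("baseline_ndvi must be in (0, 1)")
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise ValueError("cloud_fraction must be in [0, 1]")
        for name in ("grid_rows", "grid_cols", "scenes_per_year",
                     "n_plots_level1", "n_plots_level2", "cloud_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.interannual_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.year_effects is not None and len(self.year_effects) != len(self.years):
            raise ValueError("year_effects must have one entry per year")
        for ev in self.disturbance_events:
            if ev.year not in self.years:
                raise ValueError(f"disturbance year {ev.year} not in simulated years")
            if ev.ndvi_drop < 0:
                raise ValueError("ndvi_drop must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid_rows, self.grid_cols)

    @property
    def disturbance_years(self) -> tuple[int, ...]:
        return tuple(sorted({ev.year for ev in self.disturbance_events}))


@dataclass
class GroundTruth:
    """True (pre-noise, pre-cloud) fields the generator built from."""

    baseline: np.ndarray
    year_effects: dict[int, float]
    true_ndvi: dict[int, np.ndarray]
    footprints: dict[int, np.ndarray]
    plot_defoliation: pd.DataFrame | None = None


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("scenes", "clouds", "plots", "climate")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _scene_dates(year: int, n: int) -> list[dt.date]:
    doys = np.linspace(_SEASON_START_DOY, _SEASON_END_DOY, n)
    base = dt.date(year, 1, 1)
    return [base + dt.timedelta(days=int(round(d)) - 1) for d in doys]


def _block_cloud_mask(
    shape: tuple[int, int], p: float, block: int, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli(p) per block of ``block x block`` pixels; expected pixel
    fraction equals p for any block size."""
    nbr = -(-shape[0] // block)
    nbc = -(-shape[1] // block)
    blocks = rng.random((nbr, nbc)) < p
    mask = np.repeat(np.repeat(blocks, block, axis=0), block, axis=1)
    return mask[: shape[0], : shape[1]]


def _reflectance_pair(ndvi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # RED + NIR fixed at 0.5 so the NDVI ratio inverts uniquely.
    nir = 0.25 * (1.0 + ndvi)
    red = 0.25 * (1.0 - ndvi)
    return red, nir


def simulate_scenes(
    config: SimulationConfig,
) -> tuple[dict[int, list[SceneStack]], GroundTruth]:
    """Generate per-year scene stacks plus the ground truth they encode.

    The true NDVI field of a year is ``baseline + year_effect`` with the
    disturbance drop subtracted inside footprints.  Scenes observe that
    field with iid Gaussian noise; cloudy pixels are stamped with QA /
    scene-class codes and have their reflectance replaced by a bright
    cloud value.  Scene metadata ``cloud_pct`` equals the realized
    contaminated fraction.
    """
    rngs = _streams(config.seed)
    scene_rng, cloud_rng = rngs["scenes"], rngs["clouds"]
    shape = config.shape
    baseline = np.full(shape, config.baseline_ndvi)

    if config.year_effects is not None:
        offsets = dict(zip(config.years, config.year_effects))
    else:
        draws = scene_rng.normal(0.0, config.interannual_sd, size=len(config.years))
        offsets = dict(zip(config.years, draws.tolist()))

    footprints: dict[int, np.ndarray] = {}
    drops: dict[int, np.ndarray] = {y: np.zeros(shape) for y in config.years}
    for ev in config.disturbance_events:
        mask = ev.resolve(shape)
        footprints[ev.year] = footprints.get(ev.year, np.zeros(shape, bool)) | mask
        drops[ev.year] = drops[ev.year] + ev.ndvi_drop * mask

    true_ndvi: dict[int, np.ndarray] = {}
    for y in config.years:
        field_y = baseline + offsets[y] - drops[y]
        if np.any(field_y < -1.0):
            raise ValueError(f"ndvi_drop drives true NDVI below -1 in year {y}")
        true_ndvi[y] = field_y

    scenes: dict[int, list[SceneStack]] = {}
    for y in config.years:
        year_scenes: list[SceneStack] = []
        for date in _scene_dates(y, config.scenes_per_year):
            obs = true_ndvi[y].copy()
            if config.noise_sd > 0:
                obs = obs + scene_rng.normal(0.0, config.noise_sd, size=shape)
            obs = np.clip(obs, -1.0, 1.0)
            red, nir = _reflectance_pair(obs)

            qa = np.zeros(shape, dtype=np.uint16)
            scl = np.full(shape, _SCL_VEGETATION, dtype=np.uint8)
            cloudy = _block_cloud_mask(
                shape, config.cloud_fraction, config.cloud_block, cloud_rng
            )
            if cloudy.any():
                # cycle contamination flavours over cloudy blocks
                flavour = cloud_rng.integers(0, 4, size=shape)
                qa[cloudy & (flavour == 0)] |= _QA_OPAQUE
                qa[cloudy & (flavour == 1)] |= _QA_CIRRUS
                scl_pick = np.select(
                    [flavour == 2, flavour == 3],
                    [_SCL_SHADOW, _SCL_CLOUD_HIGH],
                    default=_SCL_CLOUD_MED,
                )
                scl[cloudy] = np.where(
                    flavour[cloudy] >= 2, scl_pick[cloudy], scl[cloudy]
                )
                # flavours 0/1 keep a cloudy SCL too, so either band catches them
                scl[cloudy & (flavour < 2)] = _SCL_CLOUD_MED
                red[cloudy] = 0.4
                nir[cloudy] = 0.4
            year_scenes.append(
                SceneStack(
                    red=red,
                    nir=nir,
                    qa_bits=qa,
                    scene_class=scl,
                    date=date,
                    cloud_pct=100.0 * float(cloudy.mean()),
                )
            )
        scenes[y] = year_scenes

    truth = GroundTruth(
        baseline=baseline,
        year_effects=offsets,
        true_ndvi=true_ndvi,
        footprints=footprints,
    )
    return scenes, truth


def _plot_positions(
    n: int, shape: tuple[int, int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Regular grid with jitter: n cells tile the grid, one plot per cell
    jittered inside it, mimicking a systematic plot design at toy scale."""
    rows, cols = shape
    ncol = max(1, int(np.ceil(np.sqrt(n * cols / rows))))
    nrow = int(np.ceil(n / ncol))
    cell_h, cell_w = rows / nrow, cols / ncol
    positions = []
    for k in range(n):
        i, j = divmod(k, ncol)
        r = (i + rng.uniform(0.2, 0.8)) * cell_h
        c = (j + rng.uniform(0.2, 0.8)) * cell_w
        positions.append((min(int(r), rows - 1), min(int(c), cols - 1)))
    return positions


def simulate_plots(config: SimulationConfig, truth: GroundTruth) -> list:
    """Field records for the plot network.

    Per plot-year: ``defoliation = clamp(base + gain * local_drop + noise,
    0, 100)`` where ``local_drop`` is the pixel's baseline NDVI minus that
    year's true NDVI, so plots inside disturbance footprints report
    systematically higher defoliation in disturbance years.
    """
    from zndvi.plots import PlotRecord  # local import to avoid a cycle

    rng = _streams(config.seed)["plots"]
    shape = config.shape
    defol_sd = (
        config.defol_noise_sd
        if config.defol_noise_sd is not None
        else 100.0 * config.noise_sd
    )

    specs: list[tuple[str, str, tuple[int, int]]] = []
    for lvl, prefix, n, width in (
        ("I", "L1", config.n_plots_level1, 3),
        ("II", "L2", config.n_plots_level2, 2),
    ):
        for pid, pos in enumerate(_plot_positions(n, shape, rng), start=1):
            specs.append((f"{prefix}_{pid:0{width}d}", lvl, pos))

    records: list[PlotRecord] = []
    truth_rows = []
    for plot_id, level, (r, c) in specs:
        for y in config.years:
            drop = truth.baseline[r, c] - truth.true_ndvi[y][r, c]
            true_defol = float(
                np.clip(config.defoliation_base + config.defoliation_gain * drop, 0, 100)
            )
            noise = rng.normal(0.0, defol_sd) if defol_sd > 0 else 0.0
            defol = float(
                np.clip(
                    config.defoliation_base + config.defoliation_gain * drop + noise,
                    0,
                    100,
                )
            )
            records.append(
                PlotRecord(
                    plot_id=plot_id,
                    level=level,
                    row=r,
                    col=c,
                    year=y,
                    defoliation_pct=defol,
                    defoliation_category=categorize_defoliation(defol),
                )
            )
            truth_rows.append(
                {"plot_id": plot_id, "year": y, "true_defoliation_pct": true_defol}
            )
    truth.plot_defoliation = pd.DataFrame(truth_rows)
    return records


# Monthly climatology anchors (temperate continental): Jan..Dec.
_TMEAN_CLIM = (-1.0, 1.0, 6.0, 11.5, 16.5, 19.5, 21.5, 21.0, 16.5, 11.0, 5.0, 0.5)
_PRECIP_CLIM = (35.0, 32.0, 38.0, 45.0, 60.0, 65.0, 55.0, 50.0, 45.0, 40.0, 50.0, 45.0)


def simulate_climate(config: SimulationConfig) -> dict[str, "ClimateSeries"]:
    """Monthly temperature/precipitation per intensive-plot site.

    With ``drought_coupling`` on, disturbance years get a precipitation
    multiplier < 1 and a temperature offset > 0, so the March-August
    temperature-precipitation factor is strictly higher in those years.
    """
    from zndvi.climate import ClimateSeries

    rng = _streams(config.seed)["climate"]
    drought_years = set(config.disturbance_years) if config.drought_coupling else set()
    series: dict[str, ClimateSeries] = {}
    for s in range(1, config.n_plots_level2 + 1):
        site_id = f"L2_{s:02d}"
        site_t = rng.normal(0.0, 0.5)
        site_p = rng.normal(1.0, 0.05)
        rows = []
        for y in config.years:
            for m in range(1, 13):
                t = _TMEAN_CLIM[m - 1] + site_t + rng.normal(0.0, 0.3)
                p = max(1.0, _PRECIP_CLIM[m - 1] * site_p + rng.normal(0.0, 2.0))
                if y in drought_years:
                    t += config.drought_temp_offset
                    p *= config.drought_precip_factor
                rows.append(
                    {"site_id": site_id, "year": y, "month": m,
                     "tmean_c": t, "precip_mm": p}
                )
        series[site_id] = ClimateSeries(site_id=site_id, data=pd.DataFrame(rows))
    return series
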