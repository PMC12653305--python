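"""NDVI, the standardized anomaly (Z NDVI), and the five damage classes.

The anomaly of a year is the pixelwise z-score of that year's
growing-season NDVI composite against the multi-year baseline mean and
standard deviation.  Classes partition the z axis into five half-open
bins from severe damage (z < -2) to strong regeneration (z >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES",
    "CLASS_EDGES",
    "INVALID_CLASS",
    "AnomalySet",
    "ClassDistribution",
    "ndvi",
    "z_ndvi",
    "classify",
    "class_distribution",
]

#: Class codes 0..4, worst to best.
CLASS_NAMES: tuple[str, ...] = (
    "severe damage",
    "damage",
    "moderate",
    "regeneration",
    "strong regeneration",
)

#: Lower-inclusive half-open bin edges: (-inf,-2) [-2,-1) [-1,0) [0,1) [1,inf).
CLASS_EDGES: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0)

#: Code for pixels with no defined z value.
INVALID_CLASS: int = -1

#: Pixels whose baseline standard deviation falls below this are treated
#: as degenerate (z forced to 0) instead of dividing by ~0.
DEGENERATE_STD: float = 1e-6


def ndvi(red_grid: np.ndarray, nir_grid: np.ndarray) -> np.ndarray:
    """(NIR - RED) / (NIR + RED); NaN where the sum is zero or either
    band is missing."""
    red = np.asarray(red_grid, dtype=float)
    nir = np.asarray(nir_grid, dtype=float)
    if red.shape != nir.shape:
        raise ValueError(f"shape mismatch: red {red.shape} vs nir {nir.shape}")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (nir - red) / np.where(denom == 0, 1.0, denom), np.nan)
    return out


@dataclass
class AnomalySet:
    """Per-year z grids plus the baseline statistics they derive from."""

    years: tuple[int, ...]
    ndvi: dict[int, np.ndarray]
    ndvi_mean: np.ndarray
    ndvi_std: np.ndarray
    z: dict[int, np.ndarray]
    classes: dict[int, np.ndarray] = field(default_factory=dict)
    baseline_years: tuple[int, ...] = ()
    ddof: int = 0
    n_degenerate: int = 0

    def classify_all(self) -> "AnomalySet":
        self.classes = {y: classify(self.z[y]) for y in self.years}
        return self


def z_ndvi(
    ndvi_by_year: Mapping[int, np.ndarray],
    baseline_years: Sequence[int] | None = None,
    ddof: int = 0,
    eps: float = DEGENERATE_STD,
) -> AnomalySet:
    """Standardize yearly NDVI grids against the baseline-period mean/SD.

    ``ddof=0`` (population SD) is the default convention; pass ``ddof=1``
    for the sample convention.  z is defined only where every baseline
    year is valid; pixels with baseline SD below ``eps`` are degenerate
    and get z = 0 in all years (counted in ``n_degenerate``).
    """
    years = tuple(ndvi_by_year)
    if baseline_years is None:
        baseline_years = years
    baseline_years = tuple(baseline_years)
    if len(baseline_years) < 2:
        raise ValueError("at least 2 baseline years are required")
    missing = set(baseline_years) - set(years)
    if missing:
        raise ValueError(f"baseline years not available: {sorted(missing)}")

    stack = np.stack([np.asarray(ndvi_by_year[y], dtype=float) for y in baseline_years])
    base_valid = ~np.isnan(stack).any(axis=0)
    with np.errstate(all="ignore"):
        mean = np.where(base_valid, stack.mean(axis=0), np.nan)
        std = np.where(base_valid, stack.std(axis=0, ddof=ddof), np.nan)
    degenerate = base_valid & (std < eps)

    z: dict[int, np.ndarray] = {}
    for y in years:
        grid = np.asarray(ndvi_by_year[y], dtype=float)
        with np.errstate(all="ignore"):
            zy = (grid - mean) / std
        zy = np.where(base_valid & ~np.isnan(grid), zy, np.nan)
        zy = np.where(degenerate & ~np.isnan(grid), 0.0, zy)
        z[y] = zy
    return AnomalySet(
        years=years,
        ndvi={y: np.asarray(ndvi_by_year[y], dtype=float) for y in years},
        ndvi_mean=mean,
        ndvi_std=std,
        z=z,
        baseline_years=baseline_years,
        ddof=ddof,
        n_degenerate=int(degenerate.sum()),
    )


def classify(z_grid: np.ndarray) -> np.ndarray:
    """Map z to class codes 0-4 via the half-open bins; NaN -> -1."""
    z = np.asarray(z_grid, dtype=float)
    codes = np.digitize(z, CLASS_EDGES, right=False).astype(np.int8)
    codes[np.isnan(z)] = INVALID_CLASS
    return codes


@dataclass(frozen=True)
class ClassDistribution:
    """Percent of classified pixels per class for one year."""

    year: int
    proportions: tuple[float, ...]  # five percentages
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be > 0")
        if abs(sum(self.proportions) - 100.0) > 0.05:
            raise ValueError("class proportions must sum to 100 within rounding")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "class": CLASS_NAMES,
                "percent": self.proportions,
                "n_pixels": self.n_pixels,
            }
        )


def class_distribution(class_grid: np.ndarray, year: int = 0) -> ClassDistribution:
    """Percent per class over classified (code >= 0) pixels."""
    codes = np.asarray(class_grid)
    valid = codes >= 0
    n = int(valid.sum())
    if n == 0:
        raise ValueError("class_distribution: no classified pixels")
    counts = np.bincount(codes[valid].astype(np.int64), minlength=len(CLASS_NAMES))
    pct = tuple(100.0 * c / n for c in counts)
    return ClassDistribution(year=year, proportions=pct, n_pixels=n)
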