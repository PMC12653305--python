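"""Temperature-precipitation factor (TPF) and its regression against
plot-level anomalies.

TPF = 100 * (mean of March-August monthly mean temperatures) /
(sum of March-August monthly precipitation); higher values mean a more
drought-stressed growing season.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ClimateSeries", "RegressionResult", "tpf", "fit_tpf_vs_z",
           "fit_linear", "read_climate_csv"]

TPF_MONTHS: tuple[int, ...] = (3, 4, 5, 6, 7, 8)


@dataclass
class ClimateSeries:
    """Monthly climate table for one site: columns site_id, year, month,
    tmean_c, precip_mm."""

    site_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"year", "month", "tmean_c", "precip_mm"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"climate table missing columns: {sorted(missing)}")
        if (self.data["precip_mm"] < 0).any():
            raise ValueError("precipitation must be >= 0")

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    n: int


def tpf(series: ClimateSeries, year: int) -> float:
    """100 * mean(monthly mean T, Mar-Aug) / sum(monthly P, Mar-Aug)."""
    sub = series.data[
        (series.data["year"] == year) & series.data["month"].isin(TPF_MONTHS)
    ]
    present = set(sub["month"].tolist())
    missing = set(TPF_MONTHS) - present
    if missing:
        raise ValueError(
            f"site {series.site_id} year {year}: missing months {sorted(missing)}"
        )
    total_p = float(sub["precip_mm"].sum())
    if total_p <= 0:
        raise ValueError(f"site {series.site_id} year {year}: zero precipitation")
    mean_t = float(sub["tmean_c"].mean())
    return 100.0 * mean_t / total_p


def fit_linear(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares with intercept; R^2 = 1 - RSS/TSS and
    RMSE = sqrt(mean squared residual)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    design = np.column_stack([x, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    pred = slope * x + intercept
    rss = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    return RegressionResult(slope=slope, intercept=intercept, r_squared=r2,
                            rmse=rmse, n=n)


def fit_tpf_vs_z(
    tpf_by_year: Mapping[int, float],
    plot_z_by_year: Mapping[int, float],
) -> RegressionResult:
    """Regress yearly plot-level anomaly on yearly TPF; pairs with a
    missing side are dropped; at least 3 complete pairs required."""
    years = sorted(set(tpf_by_year) & set(plot_z_by_year))
    pairs = [
        (tpf_by_year[y], plot_z_by_year[y])
        for y in years
        if np.isfinite(tpf_by_year[y]) and np.isfinite(plot_z_by_year[y])
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired years, have {len(pairs)}")
    x, y = (np.array(v) for v in zip(*pairs))
    return fit_linear(x, y)


def read_climate_csv(path) -> dict[str, ClimateSeries]:
    """Load a climate CSV (site_id, year, month, tmean_c, precip_mm)
    into per-site series."""
    df = pd.read_csv(path)
    return {
        str(site): ClimateSeries(site_id=str(site), data=g.reset_index(drop=True))
        for site, g in df.groupby("site_id")
    }
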