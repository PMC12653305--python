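"""Plot-level extraction: window means of z around monitoring plots and
the plots-per-class yearly count table."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from zndvi.indices import CLASS_NAMES, INVALID_CLASS, AnomalySet, classify

__all__ = ["PlotRecord", "PlotSeries", "extract_plot_z", "level_table",
           "records_to_frame", "records_from_frame", "read_plot_csv"]


@dataclass(frozen=True)
class PlotRecord:
    """One plot-year field observation."""

    plot_id: str
    level: str  # "I" or "II"
    row: int
    col: int
    year: int
    defoliation_pct: float
    defoliation_category: str
    notes: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.defoliation_pct <= 100.0:
            raise ValueError(
                f"defoliation_pct out of [0, 100] for {self.plot_id}/{self.year}"
            )
        if self.level not in ("I", "II"):
            raise ValueError(f"level must be 'I' or 'II', got {self.level!r}")


@dataclass
class PlotSeries:
    """Per-plot yearly anomaly summary extracted from the rasters.

    Missing plot-years (no valid pixel in the window) carry NaN z and
    class code -1.
    """

    plot_id: str
    level: str
    row: int
    col: int
    z_mean: dict[int, float] = field(default_factory=dict)
    cls: dict[int, int] = field(default_factory=dict)
    n_valid: dict[int, int] = field(default_factory=dict)


def extract_plot_z(
    anoms: AnomalySet,
    plots: Sequence[PlotRecord],
    window: int = 1,
    aggregate: str = "mean",
) -> list[PlotSeries]:
    """Summarize z in a (2*window+1)^2 pixel box around each plot.

    The default aggregation is the mean of valid member pixels, with the
    class derived from that mean; ``aggregate="mode"`` instead takes the
    modal class of member pixels.  Plots outside the grid raise with the
    offending ids listed.
    """
    if aggregate not in ("mean", "mode"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    shape = anoms.ndvi_mean.shape
    unique: dict[str, PlotRecord] = {}
    for p in plots:
        unique.setdefault(p.plot_id, p)
    bad = [
        pid
        for pid, p in unique.items()
        if not (0 <= p.row < shape[0] and 0 <= p.col < shape[1])
    ]
    if bad:
        raise ValueError(f"plots outside the grid: {sorted(bad)}")

    out: list[PlotSeries] = []
    for pid, p in unique.items():
        series = PlotSeries(plot_id=pid, level=p.level, row=p.row, col=p.col)
        r0, r1 = max(0, p.row - window), min(shape[0], p.row + window + 1)
        c0, c1 = max(0, p.col - window), min(shape[1], p.col + window + 1)
        for y in anoms.years:
            zwin = anoms.z[y][r0:r1, c0:c1]
            valid = ~np.isnan(zwin)
            n = int(valid.sum())
            series.n_valid[y] = n
            if n == 0:
                series.z_mean[y] = float("nan")
                series.cls[y] = INVALID_CLASS
            elif aggregate == "mean":
                zm = float(zwin[valid].mean())
                series.z_mean[y] = zm
                series.cls[y] = int(classify(np.array([zm]))[0])
            else:
                codes = classify(zwin[valid])
                vals, counts = np.unique(codes, return_counts=True)
                series.z_mean[y] = float(zwin[valid].mean())
                series.cls[y] = int(vals[np.argmax(counts)])
        out.append(series)
    return out


def level_table(series: Sequence[PlotSeries]) -> pd.DataFrame:
    """Counts of plots per class per year; a ``missing`` column tallies
    plot-years with no valid extraction, so per-year row sums plus
    missing equal the number of plots."""
    if len(series) == 0:
        raise ValueError("level_table requires at least one series")
    years = sorted({y for s in series for y in s.cls})
    table = pd.DataFrame(
        0, index=pd.Index(years, name="year"), columns=list(CLASS_NAMES) + ["missing"]
    )
    for s in series:
        for y in years:
            code = s.cls.get(y, INVALID_CLASS)
            if code == INVALID_CLASS:
                table.loc[y, "missing"] += 1
            else:
                table.loc[y, CLASS_NAMES[code]] += 1
    return table


def records_to_frame(records: Sequence[PlotRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def read_plot_csv(path) -> list[PlotRecord]:
    # keep_default_na=False: the literal category "None" must survive
    return records_from_frame(pd.read_csv(path, keep_default_na=False, na_values=[""]))


def records_from_frame(df: pd.DataFrame) -> list[PlotRecord]:
    from zndvi.validation import categorize_defoliation

    records = []
    for row in df.itertuples(index=False):
        cat = getattr(row, "defoliation_category", None)
        if not isinstance(cat, str) or not cat:
            cat = categorize_defoliation(row.defoliation_pct)
        records.append(
            PlotRecord(
                plot_id=str(row.plot_id),
                level=str(row.level),
                row=int(row.row),
                col=int(row.col),
                year=int(row.year),
                defoliation_pct=float(row.defoliation_pct),
                defoliation_category=cat,
                notes=str(getattr(row, "notes", "") or ""),
            )
        )
    return records
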