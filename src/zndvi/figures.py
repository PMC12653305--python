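"""Optional matplotlib figures: cumulative class-distribution bars and a
plot-by-year class heatmap.  Import requires the ``plot`` extra."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from zndvi.indices import CLASS_NAMES, ClassDistribution
from zndvi.plots import PlotSeries

# worst -> best, red to green
CLASS_COLORS = ("#d7191c", "#fdae61", "#ffffbf", "#a6d96a", "#1a9641")


def class_distribution_bars(dists: Sequence[ClassDistribution], path: Path) -> Path:
    """Stacked percent bars, one per year."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    years = [d.year for d in dists]
    fig, ax = plt.subplots(figsize=(1.2 * len(years) + 2, 4))
    bottom = np.zeros(len(years))
    for i, name in enumerate(CLASS_NAMES):
        vals = np.array([d.proportions[i] for d in dists])
        ax.bar(range(len(years)), vals, bottom=bottom, color=CLASS_COLORS[i],
               label=name, width=0.7)
        bottom += vals
    ax.set_xticks(range(len(years)), [str(y) for y in years])
    ax.set_ylabel("share of classified pixels (%)")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=8, loc="center left", bbox_to_anchor=(1.0, 0.5))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_class_heatmap(series: Sequence[PlotSeries], path: Path) -> Path:
    """Plots on rows, years on columns, cell colour = class code."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    years = sorted({y for s in series for y in s.cls})
    mat = np.full((len(series), len(years)), np.nan)
    for i, s in enumerate(series):
        for j, y in enumerate(years):
            code = s.cls.get(y, -1)
            if code >= 0:
                mat[i, j] = code
    cmap = ListedColormap(CLASS_COLORS)
    cmap.set_bad("#bbbbbb")
    norm = BoundaryNorm(np.arange(-0.5, 5.5), cmap.N)
    fig, ax = plt.subplots(figsize=(len(years) + 2, 0.25 * len(series) + 1.5))
    im = ax.imshow(mat, aspect="auto", cmap=cmap, norm=norm)
    ax.set_xticks(range(len(years)), [str(y) for y in years])
    ax.set_yticks(range(len(series)), [s.plot_id for s in series], fontsize=6)
    cbar = fig.colorbar(im, ticks=range(5))
    cbar.ax.set_yticklabels(CLASS_NAMES, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
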