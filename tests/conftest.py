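import numpy as np
import pytest

from zndvi.synthetic import DisturbanceEvent, SimulationConfig

# Deterministic per-year offsets with zero mean: healthy pixels get a
# well-conditioned baseline SD without random year effects.
YEAR_EFFECTS = (0.03, -0.03, 0.03, -0.03, 0.03, 0.0, -0.03)


@pytest.fixture
def clean_config():
    """No noise, no clouds, no disturbance, no interannual variation."""
    return SimulationConfig(
        grid_rows=10,
        grid_cols=10,
        scenes_per_year=3,
        interannual_sd=0.0,
        noise_sd=0.0,
        cloud_fraction=0.0,
        n_plots_level1=5,
        n_plots_level2=2,
        seed=7,
    )


@pytest.fixture
def disturbed_config():
    """20x20, deterministic year effects, one 40% footprint drop in 2022."""
    return SimulationConfig(
        grid_rows=20,
        grid_cols=20,
        scenes_per_year=4,
        year_effects=YEAR_EFFECTS,
        noise_sd=0.0,
        cloud_fraction=0.0,
        disturbance_events=(DisturbanceEvent(year=2022, footprint=0.4, ndvi_drop=0.3),),
        seed=11,
    )


def naive_median_composite(fields):
    """Triple-loop median oracle over a list of (grid, valid) pairs."""
    rows, cols = fields[0][0].shape
    out = np.full((rows, cols), np.nan)
    for r in range(rows):
        for c in range(cols):
            vals = [g[r, c] for g, v in fields if v[r, c]]
            if vals:
                out[r, c] = float(np.median(vals))
    return out
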