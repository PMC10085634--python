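import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from colonyscreen import iris_io
from colonyscreen.synthetic_plates import SimulationConfig, simulate_big

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_dataset(values_by_plate, n_rows, n_cols, genes=None):
    """Build a ScreenDataset from {(condition, replicate): grid array} for a
    single library plate; grids are (n_rows, n_cols)."""
    plates = [
        iris_io.PlateQuant(condition=c, library_plate=1, replicate=r,
                           values=np.asarray(v, dtype=float))
        for (c, r), v in values_by_plate.items()
    ]
    if genes is None:
        genes = [f"g{i:03d}" for i in range(n_rows * n_cols)]
    mapping = {(1, r + 1, c + 1): genes[r * n_cols + c]
               for r in range(n_rows) for c in range(n_cols)}
    layout = iris_io.layout_from_mapping(mapping)
    return iris_io.build_dataset(plates, layout)


def replicate_dataset(rep_values, condition="cond", genes=None):
    """Dataset with one condition and one column per replicate array.

    ``rep_values`` is a list of 1-D arrays (one per replicate); positions
    are laid out on a single row of a 1 x n grid (no ring structure needed).
    """
    n = len(rep_values[0])
    plates = {}
    for i, vals in enumerate(rep_values):
        plates[(condition, chr(ord("A") + i))] = np.asarray(
            vals, dtype=float).reshape(1, n)
    return make_dataset(plates, 1, n, genes=genes)


@pytest.fixture
def small_big_sim():
    """A compact large-screen simulation shared by several tests."""
    cfg = SimulationConfig(n_rows=8, n_cols=12, n_conditions=6,
                           n_replicates=3, seed=11)
    return simulate_big(cfg)


@pytest.fixture
def quiet_sim():
    """No edge effect, no plate jitter, no missingness: clean replicates."""
    cfg = SimulationConfig(n_rows=8, n_cols=12, n_conditions=8,
                           n_replicates=3, edge_multipliers=(1.0, 1.0),
                           plate_scale_cv=0.0, missing_prob=0.0,
                           mispin_prob=0.0, seed=5)
    return simulate_big(cfg)
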