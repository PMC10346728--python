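import numpy as np
import pytest

from dendrostand.competition import hegyi_ci_all
from dendrostand.growth import bai_series, reconstruct_radii
from dendrostand.io_formats import average_cores_by_tree
from dendrostand.mixed_model import build_design
from dendrostand.synthetic_data import SimulationConfig, simulate_dataset

DEFAULT_SEED = 7
MODEL_PERIOD = (1993, 2016)  # most recent 24 years of the default span


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic stand shared across the suite."""
    return simulate_dataset(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_design(default_dataset):
    """Assembled growth records (BAI, age, CI, climate) for the stand."""
    climate, stand, rings, truth = default_dataset
    ci = hegyi_ci_all(stand)
    bai = {}
    for tr in average_cores_by_tree(rings):
        row = stand.tree(tr.tree_id)
        bai[tr.tree_id] = bai_series(reconstruct_radii(tr, float(row["dbh"])))
    return build_design(bai, ci, climate, MODEL_PERIOD)


def make_rings(seed: int, n: int = 8, length: int = 42, first_year: int = 1975):
    """Small ad-hoc ring collections for IO and chronology unit tests."""
    from dendrostand.io_formats import RingSeries

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        w = np.round(rng.lognormal(0.0, 0.3, length), 2)
        w = np.clip(w, 0.01, 9.89)
        out.append(RingSeries(f"S{i:02d}A", f"S{i:02d}", first_year, w))
    return out
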