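import numpy as np
import pandas as pd
import pytest

import aquamon as am


@pytest.fixture(scope="session")
def small_design():
    """A reduced acquisition design for fast unit tests."""
    return am.DesignSpec(sample_types=("seedling",), n_seeds_per_type=6,
                         n_positions=2, n_scans=2, days=(4, 6, 8, 10))


@pytest.fixture(scope="session")
def small_truth(small_design):
    return am.make_preset("seedling_like", small_design)


@pytest.fixture(scope="session")
def small_archive(small_truth):
    return am.generate_experiment(small_truth.design, small_truth, rng_seed=42)


@pytest.fixture(scope="session")
def stage_design():
    """All 12 monitored days, fewer replicates: enough for stage detection."""
    return am.DesignSpec(sample_types=("seedling",), n_seeds_per_type=9,
                         n_positions=2, n_scans=2)


@pytest.fixture(scope="session")
def stage_archive(stage_design):
    truth = am.make_preset("seedling_like", stage_design)
    return am.generate_experiment(truth.design, truth, rng_seed=7)


def make_table(values, wavelengths=None, meta=None):
    values = np.atleast_2d(np.asarray(values, float))
    if wavelengths is None:
        wavelengths = np.arange(values.shape[1], dtype=float)
    if meta is None:
        meta = pd.DataFrame({"row": np.arange(values.shape[0])})
    return am.SpectraTable(np.asarray(wavelengths, float), values, meta)


@pytest.fixture
def table_factory():
    return make_table
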