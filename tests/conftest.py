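import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("repro", derandomize=True, deadline=None)
_hsettings.load_profile("repro")

from socmicro.dyad import DyadMatrix
from socmicro.synthetic_colony import SimulationConfig, simulate_colony


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def small_config(**overrides):
    """A fast, small merged-colony scenario for unit tests."""
    params = dict(
        n_colonies=2,
        bats_per_colony=4,
        n_taxa=30,
        n_days=30,
        merge_day=5,
        n_hours=24,
        hours_per_day=6,
        n_periods=48,
        sequencing_depth=5000,
        sampling_schedule={
            "A01": [0], "A02": [0],
            "A03": [3, 10, 20], "B01": [3, 10, 20],
        },
        seed=11,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_colony():
    cfg = SimulationConfig(
        n_colonies=2, bats_per_colony=4, n_taxa=30, n_days=30, merge_day=5,
        n_hours=24, hours_per_day=6, n_periods=48, sequencing_depth=5000,
        sampling_schedule={
            "A01": [0], "A02": [0],
            "A03": [3, 10, 20], "B01": [3, 10, 20],
        },
        seed=11,
    )
    return simulate_colony(cfg)


def symmetric_dyad_matrix(rng, n, ids=None, diag=np.nan):
    a = rng.normal(size=(n, n))
    a = np.triu(a, 1)
    a = a + a.T
    np.fill_diagonal(a, diag)
    ids = ids or [f"b{i:02d}" for i in range(n)]
    return DyadMatrix(ids, a)
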