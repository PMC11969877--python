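import numpy as np
import pytest

from ebbtrack import synthetic_data
from ebbtrack.core_data import AnalysisConfig, WaterLevelSeries, read_dataset


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixtures") / "small42"
    synthetic_data.make_fixture(d, seed=42, profile="small")
    return d


@pytest.fixture(scope="session")
def dataset(fixture_dir):
    return read_dataset(fixture_dir, AnalysisConfig())


@pytest.fixture()
def flat_series():
    """Two constant-level stations for interpolation tests."""
    t = np.arange(0, 7200, 600, dtype=np.int64)

    def make(station_id, chainage, level):
        return WaterLevelSeries(station_id, chainage, t.copy(), np.full(t.size, level))

    return make


@pytest.fixture()
def symmetric_tide():
    cfg = synthetic_data.SimConfig(
        seed=5, duration_days=10.0, ebb_frac_mouth=0.5, ebb_frac_upstream=0.5,
        station_chainages=(50.0,), tide_noise_sigma=0.0,
    )
    return synthetic_data.simulate_tides(cfg)[0]


@pytest.fixture()
def asymmetric_tide():
    cfg = synthetic_data.SimConfig(
        seed=5, duration_days=10.0, ebb_frac_mouth=0.677, ebb_frac_upstream=0.677,
        station_chainages=(50.0,), tide_noise_sigma=0.0,
    )
    return synthetic_data.simulate_tides(cfg)[0]
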