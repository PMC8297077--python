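import numpy as np
import pandas as pd
import pytest

from clearwater.series import SiteSeries
from clearwater.synthetic import SimParams, emulate_dataset


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Two years, four sites, 5 planted grazing pulses per site, no noise."""
    params = SimParams(seed=42, noise_sd=0.0, pulses_per_site=5)
    return emulate_dataset(params)


@pytest.fixture(scope="session")
def noisy_dataset():
    params = SimParams(seed=7, noise_sd=0.05)
    return emulate_dataset(params)


def make_series(site="s1", **cols) -> SiteSeries:
    """Small hand-built weekly series; unspecified detection variables get
    neutral constants."""
    n = len(next(iter(cols.values())))
    base = {
        "date": pd.date_range("2015-03-02", periods=n, freq="7D"),
        "secchi_depth": np.full(n, 2.0),
        "chl_a": np.full(n, 10.0),
        "turbidity": np.full(n, 3.0),
        "rotifera": np.full(n, 50.0),
        "cladocera": np.full(n, 20.0),
        "copepoda": np.full(n, 30.0),
    }
    for k, v in cols.items():
        base[k] = np.asarray(v, dtype=float)
    return SiteSeries(site, pd.DataFrame(base))


@pytest.fixture
def series_factory():
    return make_series
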