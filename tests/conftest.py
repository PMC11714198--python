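import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from soilcast import SimConfig, generate, fill_missing_linear

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_series():
    """Six synthetic days with a little missingness (432 points)."""
    return generate(SimConfig(n_days=6, missing_rate=0.02, seed=7))


@pytest.fixture(scope="session")
def clean_series(small_series):
    return fill_missing_linear(small_series)


@pytest.fixture()
def csv_file(tmp_path):
    """A tiny hand-written sensor CSV with one missing cell."""
    path = tmp_path / "log.csv"
    pd.DataFrame({
        "timestamp": pd.date_range("2024-02-14", periods=3, freq="20min"),
        "soil_temperature": [25.0, np.nan, 26.0],
        "air_temperature": [20.0, 21.0, 22.0],
    }).to_csv(path, index=False)
    return path
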