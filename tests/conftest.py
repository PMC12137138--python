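import numpy as np
import pandas as pd
import pytest

from riverc14.atmosphere import AtmosphericRecord
from riverc14.simulate import default_record


@pytest.fixture(scope="session")
def record():
    """Bundled parametric bomb-curve record extended through 2023."""
    return default_record(2023)


@pytest.fixture
def flat_record():
    """Constant atmospheric record (value 1.25) covering 1990-2023."""
    years = np.arange(1990, 2024)
    return AtmosphericRecord(years, np.full(years.size, 1.25))


@pytest.fixture
def obs_csv(tmp_path):
    """Small well-formed observations CSV (3 valid rows)."""
    path = tmp_path / "obs.csv"
    pd.DataFrame(
        {
            "site_id": ["A", "A", "B"],
            "year": [2000, 2000, 2010],
            "date": ["2000-05-01", "2000-05-01", None],
            "compound": ["DIC", "CO2", "CH4"],
            "f14c": [1.0, 0.98, 0.85],
            "sigma_f14c": [0.004, 0.004, 0.005],
            "latitude": [51.5, 51.5, -3.1],
            "longitude": [-0.1, -0.1, 37.4],
            "catchment_area_km2": [120.0, 120.0, 8.0],
            "lithology_raw": ["SC", "SC", "MT"],
            "biome_raw": [4, 4, 1],
        }
    ).to_csv(path, index=False)
    return path
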