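import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import agrocf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return agrocf.load_table1_fixture()


@pytest.fixture(scope="session")
def ef_table() -> agrocf.EmissionFactorTable:
    return agrocf.default_emission_factor_table()


@pytest.fixture(scope="session")
def noiseless_rotation() -> agrocf.RotationData:
    return agrocf.generate_rotation(agrocf.GeneratorConfig(seed=7).noiseless())


@pytest.fixture()
def season_csv(tmp_path):
    """Write a minimal one-row wheat season CSV and return its path."""

    def _write(rows, name="records.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write
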