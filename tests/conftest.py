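from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from canalbedo.spectral_io import WavelengthGrid

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20180515)


@pytest.fixture()
def noon() -> datetime:
    return datetime(2018, 10, 1, 12, 0, tzinfo=timezone.utc)
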