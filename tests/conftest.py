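import math

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")

from mprtws import (
    ScoreBand,
    default_band_table,
)


@pytest.fixture(scope="session")
def mprt_table():
    return default_band_table("MPRT-WS")


@pytest.fixture(scope="session")
def news_table():
    return default_band_table("NEWS")


@pytest.fixture(scope="session")
def toy_bands():
    """A six-band toy parameter table used throughout the scoring tests."""
    return (
        ScoreBand(-math.inf, 40, 3),
        ScoreBand(40, 50, 1),
        ScoreBand(50, 90, 0),
        ScoreBand(90, 110, 1),
        ScoreBand(110, 130, 2),
        ScoreBand(130, math.inf, 3),
    )
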