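import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pyra import (  # noqa: E402
    CycleConfig,
    DailySeries,
    PairedSeries,
    make_triplet,
    scenario1,
    scenario2,
)


@pytest.fixture(scope="session")
def s1_triplet():
    """Scenario 1 (seasonal, no trend), moderate noise, fixed seed."""
    return make_triplet(scenario1(seed=20240101))


@pytest.fixture(scope="session")
def s2_triplet():
    """Scenario 2 (uniform decline), default noise, fixed seed."""
    return make_triplet(scenario2(seed=20240102))


@pytest.fixture(scope="session")
def s1_noisefree_triplet():
    return make_triplet(scenario1(seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def s2_noisefree_triplet():
    return make_triplet(scenario2(seed=0, noise_sd=0.0))


@pytest.fixture
def two_cycle_series():
    """Two identical fully logged 365-day cycles."""
    C = 365
    values = np.tile(50.0 + np.arange(C) % 7, 2)
    return DailySeries(
        "siteA", CycleConfig(), np.arange(1, 2 * C + 1), values, np.ones(2 * C)
    )


def paired_from_values(y1, y2, C=365, site="s"):
    y1 = np.asarray(y1, dtype=float)
    k = np.arange(1, len(y1) + 1)
    return PairedSeries(CycleConfig(C=C), np.full(len(y1), site, object), k, y1, y2)


@pytest.fixture
def make_paired():
    return paired_from_values
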