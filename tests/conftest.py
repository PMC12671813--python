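"""Shared fixtures: canonical simulated deployments, reused across modules.

Session scope keeps the heavier simulations to one run each; sampling is
coarsened where a test only needs daily-scale structure.
"""

import logging

import pytest
from hypothesis import HealthCheck, settings

from physiotag.scenarios import (
    event_benchmark_series,
    migrant_scenario,
    resident_scenario,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

logging.getLogger("physiotag").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def resident():
    """(field, series) for the residence scenario; 2-min sampling."""
    return resident_scenario(seed=7, sampling_s=120)


@pytest.fixture(scope="session")
def migrant():
    """(field, series) for the spawning-potential scenario; 1-min sampling."""
    return migrant_scenario(seed=11, sampling_s=60)


@pytest.fixture(scope="session")
def event_series():
    """(field, series) with exactly 20 implanted thermal events."""
    return event_benchmark_series(seed=3)
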