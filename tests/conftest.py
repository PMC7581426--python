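"""Shared fixtures: small simulated sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from cfpc import DeconvParams, SimParams, simulate_cf_population, zscore


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(seed=1, n_cf=8, duration=120.0)


@pytest.fixture(scope="session")
def small_session(small_params):
    """(trace, rois, truth) for an 8-ROI, 120 s resting-state simulation."""
    return simulate_cf_population(small_params)


@pytest.fixture(scope="session")
def small_z(small_session):
    trace, _, _ = small_session
    return zscore(trace)


@pytest.fixture(scope="session")
def default_deconv() -> DeconvParams:
    return DeconvParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
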