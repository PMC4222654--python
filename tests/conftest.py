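"""Shared fixtures: trajectories are expensive enough to compute once."""

from __future__ import annotations

import dataclasses

import pytest

from denitvial import (
    DEFAULT_PARAMS,
    all_batch_treatments,
    batch_treatment,
    simulate,
)


@pytest.fixture(scope="session")
def nine_batches():
    """Trajectories of the nine reference batch treatments."""
    return {b: simulate(t) for b, t in all_batch_treatments().items()}


@pytest.fixture(scope="session")
def batch7(nine_batches):
    return nine_batches[7]


@pytest.fixture(scope="session")
def batch4(nine_batches):
    return nine_batches[4]


@pytest.fixture(scope="session")
def calibration_treatment():
    """Batch-4 conditions trimmed to a 60 h horizon, the default for fits."""
    return dataclasses.replace(batch_treatment(4), horizon=60.0)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS
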