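"""Shared fixtures: small noiseless phantom, fitted tensor, derived maps."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dkparc import (
    PhantomSpec,
    assemble_maps,
    fit_tensor,
    generate_labels,
    simulate_dwi,
)

settings.register_profile(
    "suite", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(grid_size=32, noise_sigma=0.0, seed=3)


@pytest.fixture(scope="session")
def phantom_labels(phantom_spec):
    return generate_labels(phantom_spec)


@pytest.fixture(scope="session")
def phantom_dwi(phantom_spec, phantom_labels):
    return simulate_dwi(phantom_labels, phantom_spec)


@pytest.fixture(scope="session")
def phantom_tensor(phantom_dwi):
    return fit_tensor(phantom_dwi)


@pytest.fixture(scope="session")
def phantom_maps(phantom_tensor):
    return assemble_maps(phantom_tensor)


def sorted_triple(rng, low=1e-4, high=3e-3):
    """Random positive eigenvalue triple sorted descending."""
    t = np.sort(rng.uniform(low, high, 3))[::-1]
    return float(t[0]), float(t[1]), float(t[2])
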