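"""Shared fixtures.

The wild-type growing-disc simulation is expensive (a few minutes) and is
shared session-wide by the furrow-kinetics, growth-termination, anisotropy
and gradient-scaling checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from eyedisc import ModelParameters, EyeDiscSimulation


@pytest.fixture(scope="session")
def wt_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def wt_result(wt_params):
    """Full wild-type run at the packaged production resolution."""
    sim = EyeDiscSimulation(wt_params)
    return sim.run(80.0, output_every_h=1.0, snapshots_at_h=(20.0, 40.0, 60.0))


@pytest.fixture(scope="session")
def coarse_params() -> ModelParameters:
    """Reduced-resolution configuration for perturbation screens."""
    return ModelParameters(target_edge=6.0)


def pytest_addoption(parser):
    pass


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
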