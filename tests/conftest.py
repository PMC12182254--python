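"""Shared fixtures: small simulated datasets and reproducible generators."""

import numpy as np
import pytest
from hypothesis import settings

from latentsna import BehaviorTable, ConnectomeSet, SimulationDesign, \
    simulate_dataset

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-biomarker dataset reused across read-only tests."""
    design = SimulationDesign(V=12, N=40, P=3, biomarker_nodes=range(4),
                              cross_cov=0.35, tau2=0.4, sigma2=0.5, seed=99,
                              condition="fixture")
    return simulate_dataset(design)


@pytest.fixture
def tiny_connectome(rng):
    v, n = 5, 4
    mats = rng.standard_normal((n, v, v))
    mats = 0.5 * (mats + mats.transpose(0, 2, 1))
    mats[:, np.arange(v), np.arange(v)] = 0.0
    return ConnectomeSet(mats, condition="tiny")


@pytest.fixture
def tiny_behavior(rng):
    vals = rng.standard_normal((4, 2))
    return BehaviorTable(vals, category="tinycat")
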