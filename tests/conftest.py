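"""Shared fixtures: printed-count verification data and small simulated studies."""

import numpy as np
import pandas as pd
import pytest

from sibqtl.simulate import SimConfig, simulate_family
from sibqtl.verification import reconstruct_verification_family


@pytest.fixture(scope="session")
def table2_individuals():
    """Per-individual reconstruction of the printed verification counts."""
    return reconstruct_verification_family()


@pytest.fixture(scope="session")
def small_family():
    """One deterministic small family used across module tests."""
    cfg = SimConfig(n_offspring=200, n_markers=40, pool_size=20, seed=11)
    ped, phen = simulate_family(cfg)
    return cfg, ped, phen


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
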