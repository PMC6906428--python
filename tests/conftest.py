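"""Shared fixtures: small synthetic populations generated at test time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from seedfill import SimConfig
from seedfill.simulate import simulate_ril_genotypes


@pytest.fixture(scope="session")
def small_population():
    """208-line RIL population on the default desk-scale map (seed 0)."""
    cfg = SimConfig()
    rng = np.random.default_rng(0)
    geno, gmap = simulate_ril_genotypes(cfg, rng)
    return cfg, geno, gmap


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def dap_times():
    return np.array([10, 15, 20, 25, 30, 35, 40, 43, 46, 49, 52, 55, 58, 61], float)
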