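"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

import stesi


@pytest.fixture(scope="session")
def toy_head():
    """32-electrode, 400-source, 50-region spherical head (seed 7)."""
    return stesi.build_spherical_head(n_electrodes=32, n_sources_full=400,
                                      n_regions=50, rng_seed=7)


@pytest.fixture(scope="session")
def mini_head():
    """Smaller head for expensive simulator tests."""
    return stesi.build_spherical_head(n_electrodes=16, n_sources_full=120,
                                      n_regions=20, rng_seed=11)


@pytest.fixture(scope="session")
def mini_spike_bank(mini_head):
    """Spike bank from a single 10-s portion per region (fast)."""
    cfg = stesi.NMMConfig(rng_seed=5, portions_per_region=1,
                          portion_length=10.0, order=1)
    return stesi.build_spike_bank(mini_head, cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
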