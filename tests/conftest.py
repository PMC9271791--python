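"""Shared phantom fixtures.

Phantom generation is deterministic (seeded), so expensive bundles are
session-scoped and shared across test modules.
"""

import numpy as np
import pytest

from nwu_kit import PhantomSpec, make_ctp_series, make_phantom


@pytest.fixture(scope="session")
def std_bundle():
    """The standard phantom: 25% uptake, 2 HU noise, no HT, no tilt."""
    return make_phantom(PhantomSpec(uptake_fraction=0.25, noise_sd=2.0, seed=1))


@pytest.fixture(scope="session")
def w0_bundle():
    """No-uptake phantom: the infarct region is statistically normal tissue."""
    return make_phantom(PhantomSpec(uptake_fraction=0.0, noise_sd=2.0, seed=1))


@pytest.fixture(scope="session")
def quiet_bundle():
    """Noise-free 25%-uptake phantom for exact density arithmetic."""
    return make_phantom(PhantomSpec(uptake_fraction=0.25, noise_sd=0.0, seed=1))


@pytest.fixture(scope="session")
def ctp_bundle(std_bundle):
    """Noise-free CTP forward model: core ratio 0.2, 6 s core delay."""
    bundle = make_phantom(PhantomSpec(uptake_fraction=0.10, noise_sd=2.0, seed=1))
    ctp = make_ctp_series(
        bundle, cbf_core_ratio=0.2, delay_core_s=6.0, noise_sd=0.0, seed=1
    )
    return bundle, ctp


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
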