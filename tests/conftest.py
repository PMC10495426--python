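import logging

import pytest

from nfert import WorldConfig, generate_world, run_pipeline

logging.getLogger("nfert").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def clean_world():
    """Noise-free world: the exact-recovery regime."""
    cfg = WorldConfig(seed=3, noise_sd=0.0, missing_block=None, missing_frac=0.0)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def clean_result(clean_world):
    return run_pipeline(clean_world)


@pytest.fixture(scope="session")
def noisy_world():
    """Default study conditions: noisy panels, 1962-1972 gap + 6% missing."""
    return generate_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def noisy_result(noisy_world):
    return run_pipeline(noisy_world)
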