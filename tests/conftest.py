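import numpy as np
import pytest

from mrbpe import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def noiseless_case():
    """Default-geometry phantom with no noise, moderate density."""
    cfg = PhantomConfig(fgt_fraction=0.2, noise_sigma=0.0, rng_seed=11)
    t2w, dce, truth = generate_phantom(cfg)
    return t2w, dce, truth


@pytest.fixture(scope="session")
def noisy_case():
    cfg = PhantomConfig(fgt_fraction=0.125, noise_sigma=0.02, rng_seed=12)
    t2w, dce, truth = generate_phantom(cfg)
    return t2w, dce, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
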