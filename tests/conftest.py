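import numpy as np
import pytest

from hemoseg.phantom import PhantomConfig, extended_tissue_library, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_phantom():
    """A seeded 4-class phantom at reduced pixel counts (deterministic)."""
    specs = extended_tissue_library(4, scale=0.2)
    config = PhantomConfig(tissues=specs, seed=7)
    values, labels = generate_phantom(config, np.random.default_rng(7))
    return values, labels, specs


@pytest.fixture(scope="session")
def seven_class_phantom():
    specs = extended_tissue_library(7, scale=0.25)
    config = PhantomConfig(tissues=specs, seed=11)
    values, labels = generate_phantom(config, np.random.default_rng(11))
    return values, labels, specs
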