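import numpy as np
import pytest

from polarmod.config import AcquisitionConfig, PopulationParams


@pytest.fixture
def default_acq():
    return AcquisitionConfig()


@pytest.fixture
def small_acq():
    """Small field of view for fast rendering tests (full-length movie)."""
    return AcquisitionConfig(image_shape=(128, 128))


def make_population(**overrides):
    base = dict(n_molecules=10, seed=0)
    base.update(overrides)
    return PopulationParams(**base)


@pytest.fixture
def make_pop():
    return make_population
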