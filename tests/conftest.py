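import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from npqcell import build_reference_protocol
from npqcell.experiments import train_reference_model
from npqcell.simulate import component_bases

#: Master seed of the canonical test experiment; all stage seeds are
#: spawned from it.
MASTER_SEED = 0


@pytest.fixture(scope="session")
def protocol():
    return build_reference_protocol()


@pytest.fixture(scope="session")
def bases(protocol):
    return component_bases(protocol)


@pytest.fixture(scope="session")
def trained(protocol):
    """Canonical trained model plus its four training populations."""
    model, sets = train_reference_model(MASTER_SEED, n_per_pop=300)
    return model, sets
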