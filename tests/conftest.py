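import numpy as np
import pytest

from sirnapbpk import assemble_parameterization, load_species_physiology

#: solver settings used throughout the suite; accurate enough for every
#: asserted tolerance while keeping the run short
FAST = dict(rtol=1e-6, atol=1e-10)


@pytest.fixture(scope="session")
def mouse_phys():
    return load_species_physiology("mouse")


@pytest.fixture(scope="session")
def mouse_param():
    return assemble_parameterization("siRNA-1", "mouse")


@pytest.fixture(scope="session")
def human_param():
    return assemble_parameterization("siRNA-2", "human")
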