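import numpy as np
import pytest

import stentdeg as sd


@pytest.fixture(scope="session")
def law():
    return sd.MaterialLaw()


@pytest.fixture(scope="session")
def kinetics():
    return sd.KineticParams()


@pytest.fixture()
def beam9():
    return sd.toy_lattice("single_beam", 9, length=10.0)


@pytest.fixture()
def ring64():
    return sd.toy_lattice("ring", 64, radius=1.5)


def zero_stress_kinetics(**overrides):
    """Kinetics with every coupling switched off: pure first-order decay."""
    base = dict(
        stress_sensitivity=0.0,
        source_coeff=0.0,
        release_coeff=0.0,
        alpha_m_inf=0.0,
        k=0.0,
    )
    base.update(overrides)
    return sd.KineticParams(**base)
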