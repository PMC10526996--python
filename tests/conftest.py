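import numpy as np
import pytest
from hypothesis import settings

from dermaflux.domain import SkinBarrier, microns_to_cm

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def skin_timescale() -> SkinBarrier:
    """Ethanol through dry stratum corneum, response-time parameterisation."""
    return SkinBarrier(D=3e-11, L=microns_to_cm(15.0))


@pytest.fixture
def skin_kskin() -> SkinBarrier:
    """Ethanol through dry stratum corneum, permeability parameterisation."""
    return SkinBarrier(D=5e-10, L=microns_to_cm(15.0))


@pytest.fixture
def unit_skin() -> SkinBarrier:
    return SkinBarrier(D=1.0, L=1.0, C0=1.0)


@pytest.fixture(scope="session")
def t_grid() -> np.ndarray:
    """Dense dimensionless time grid on (0, 5] for ordering/limit checks."""
    return np.linspace(0.01, 5.0, 400)
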