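import pytest

from epimuscular import SyntheticSpec
from epimuscular.reference import (
    control_stiffness,
    scale_factor_r,
    tissue_integration_stiffness,
)


@pytest.fixture(scope="session")
def control_set():
    """Calibrated stiffness of the normal-connectivity group."""
    return control_stiffness()


@pytest.fixture(scope="session")
def ti_set():
    """Calibrated stiffness of the tissue-integrating mesh group."""
    return tissue_integration_stiffness()


@pytest.fixture(scope="session")
def r_factors():
    return scale_factor_r()


@pytest.fixture()
def noiseless_spec(control_set, r_factors):
    """Noiseless two-animal synthetic experiment from the control truth."""
    return SyntheticSpec(
        truth=control_set, r=r_factors, n_animals=2, noise_sd_N=0.0, seed=7
    )
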