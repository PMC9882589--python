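import numpy as np
import pytest

from jkte import (
    AcquisitionConfig,
    TE_FSE_MS,
    make_vial_phantom,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def te_fse():
    return np.asarray(TE_FSE_MS)


@pytest.fixture(scope="session")
def vial_phantom():
    return make_vial_phantom((128, 128))


@pytest.fixture(scope="session")
def noiseless_kspace(vial_phantom):
    acq = AcquisitionConfig(noise_sd=0.0, seed=0)
    return simulate_acquisition(vial_phantom, acq)


@pytest.fixture(scope="session")
def noisy_kspace(vial_phantom):
    acq = AcquisitionConfig(noise_sd=2.0, seed=1)
    return simulate_acquisition(vial_phantom, acq)
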