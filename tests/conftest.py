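import numpy as np
import pytest

from adnexal_dce.aif import blood_to_plasma, population_blood_curve, weinmann_aif
from adnexal_dce.protocol import AcquisitionProtocol


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    """The default dynamic protocol: 7.6 s frames, 50 frames, 10 s lead."""
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def times(protocol):
    return protocol.times()


@pytest.fixture(scope="session")
def aif_model(protocol):
    """Population AIF with literature constants on the default protocol."""
    return weinmann_aif(dose=protocol.dose_mmol_per_kg,
                        onset_time=protocol.injection_time_s)


@pytest.fixture(scope="session")
def cp(aif_model, times):
    """Plasma concentration input on the acquisition grid."""
    return blood_to_plasma(population_blood_curve(aif_model, times),
                           aif_model.hct)


@pytest.fixture()
def rng():
    return np.random.default_rng(20190401)
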