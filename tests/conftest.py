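import numpy as np
import pytest

from flowres.flow_model import (
    BLOOD,
    HarmonicDecomposition,
    VesselModel,
    WomersleyField,
    decompose,
    make_waveform,
)
from flowres.virtual_scanner import AcquisitionSettings, acquire


@pytest.fixture(scope="session")
def fluid():
    return BLOOD


@pytest.fixture(scope="session")
def vessel():
    return VesselModel()


@pytest.fixture(scope="session")
def waveform():
    return make_waveform()


@pytest.fixture(scope="session")
def decomp(waveform):
    return decompose(waveform, 8)


@pytest.fixture(scope="session")
def field(decomp, vessel, fluid):
    return WomersleyField(decomp, vessel, fluid)


@pytest.fixture(scope="session")
def poiseuille_vessel():
    # short tube so that fine-voxel acquisitions stay cheap
    return VesselModel(radius=0.0125, length=0.006)


@pytest.fixture(scope="session")
def poiseuille_decomp(poiseuille_vessel):
    # steady flow with 1 m/s centreline velocity: Q0 = U_max pi R^2 / 2
    q0 = 0.5 * np.pi * poiseuille_vessel.radius**2
    return HarmonicDecomposition(2.0 * np.pi / 0.9, np.array([q0 + 0j]))


@pytest.fixture(scope="session")
def poiseuille_field(poiseuille_decomp, poiseuille_vessel, fluid):
    return WomersleyField(poiseuille_decomp, poiseuille_vessel, fluid)


@pytest.fixture(scope="session")
def fine_poiseuille_vox(poiseuille_field, poiseuille_vessel):
    """Steady parabolic flow acquired at 0.5 mm voxels, one frame."""
    settings = AcquisitionSettings(voxel_size=0.5)
    return acquire(poiseuille_field, poiseuille_vessel, settings, 0.9, frame_times=[0.0])
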