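import numpy as np
import pytest

from irscatter.events import IrradiationEvent
from irscatter.geometry import PatientPhantom, RoomModel, Table, default_room
from irscatter.spectrum import Spectrum
from irscatter.transport import DetectorPoint


@pytest.fixture
def case_a_event() -> IrradiationEvent:
    """Single-event experimental exposure: 79 kVp, 0.3 mm Cu, 835 cm^2,
    PKA 4.1 Gy*cm^2, Kair 17.6 mGy."""
    return IrradiationEvent(
        event_id="a0001", t_start=1_600_000_000.0, duration=120.0,
        event_type="fluoroscopy", kvp=79.0, filtration_cu=0.3,
        field_area=835.0, p_ka=4.1, k_air_ref=17.6,
    ).validate()


@pytest.fixture
def bomab_room() -> RoomModel:
    return default_room()


@pytest.fixture
def water_slab_room() -> RoomModel:
    """20 cm water slab centred on the isocenter, no table: the toy
    geometry for estimator cross-checks."""
    phantom = PatientPhantom(kind="prism", prism_size=(0.3, 0.3, 0.2),
                             material="water")
    return RoomModel(phantom=phantom, table=Table(enabled=False))


@pytest.fixture
def chest_point() -> DetectorPoint:
    return DetectorPoint("chest", (0.70, -0.20, 0.45), "trunk dosemeter")


def mono_spectrum(energy_kev: float) -> Spectrum:
    """Single-bin (quasi-monoenergetic) spectrum centred on energy_kev."""
    return Spectrum(
        energy_edges=np.array([energy_kev - 0.5, energy_kev + 0.5]),
        weights=np.array([1.0]),
        kvp=energy_kev + 1.0,
    )
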