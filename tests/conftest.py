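import numpy as np
import pytest

from evapollps.evaporation import AmbientConditions, DropletGeometry
from evapollps.hydrodynamics import FluidProperties
from evapollps.synthetic import DEFAULT_BINODAL, DEFAULT_TIE_SLOPE


@pytest.fixture
def paper_droplet() -> DropletGeometry:
    """0.5 uL droplet at 45 degrees: the canonical experimental geometry."""
    return DropletGeometry.from_volume(0.5e-9, np.deg2rad(45.0))


@pytest.fixture
def room_ambient() -> AmbientConditions:
    """60% RH room conditions with default vapor properties."""
    return AmbientConditions.from_relative_humidity(0.6)


@pytest.fixture
def fluid() -> FluidProperties:
    return FluidProperties()


@pytest.fixture
def binodal():
    """The packaged synthetic PEG-8000/dextran-10000-like binodal."""
    return DEFAULT_BINODAL


@pytest.fixture
def tie_slope() -> float:
    return DEFAULT_TIE_SLOPE
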