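import numpy as np
import pytest

from dropsense import (
    CalibrationSchedule,
    DropGeometry,
    HydrogelSensor,
    MeasurementSetup,
    PhysicalConstants,
)


@pytest.fixture
def constants() -> PhysicalConstants:
    return PhysicalConstants()


@pytest.fixture
def sensor() -> HydrogelSensor:
    """Default sensor at the B = 0.25 operating point."""
    return HydrogelSensor()


@pytest.fixture
def geometry() -> DropGeometry:
    return DropGeometry()


@pytest.fixture
def setup(geometry) -> MeasurementSetup:
    """An empty-drop measurement with mild H2O2 carry-over."""
    return MeasurementSetup(geometry=geometry, ch0=2.0)


@pytest.fixture
def schedule() -> CalibrationSchedule:
    """The standard 3-point staircase with first-order mixing."""
    return CalibrationSchedule()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
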