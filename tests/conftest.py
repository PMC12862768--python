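import numpy as np
import pytest

from smfretsim.efficiency import EfficiencyModel
from smfretsim.landscapes import BistableLandscape, HarmonicLandscape, ThermoState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def thermo_ex1():
    """High-temperature thermodynamic state of the single-state example."""
    return ThermoState(beta=1.339, temperature_label=378.0)


@pytest.fixture
def thermo_ex2():
    """Room-temperature state of the two-state example."""
    return ThermoState(beta=1.679, temperature_label=300.0)


@pytest.fixture
def harmonic40():
    return HarmonicLandscape(k_harmonic=0.025, center=40.0)


@pytest.fixture
def harmonic65():
    return HarmonicLandscape(k_harmonic=0.025, center=65.0)


@pytest.fixture
def bistable():
    return BistableLandscape(k_bistable=1e-4, center=50.0, well_offset=15.0)


@pytest.fixture
def forster56():
    return EfficiencyModel.forster(R0=56.0)


@pytest.fixture
def restricted56():
    return EfficiencyModel.restricted_dye(R0=56.0)
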