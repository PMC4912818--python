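import numpy as np
import pytest

from retentostat import PirtParameters, ReactorConfig
from retentostat.synthetic import NoiseModel


@pytest.fixture(scope="session")
def study_config() -> ReactorConfig:
    """The chosen operating point: 1.4 L culture, 35 mL/h, 1.2 L mixing
    vessel, feed glucose 20 → 7.5 g/L."""
    return ReactorConfig(v=1.4, v_s=1.2, phi_v=0.035, c_s_mc=20.0, c_s_mr=7.5)


@pytest.fixture(scope="session")
def design_params() -> PirtParameters:
    """Design-stage kinetics: Y = 0.5 g/g with the anaerobic-derived
    maintenance guess of 0.011 g/gX/h."""
    return PirtParameters(y_xs_max=0.5, m_s=0.011)


@pytest.fixture(scope="session")
def fitted_params() -> PirtParameters:
    """Experimentally fitted maintenance: 0.00703 g/gX/h
    (0.039 mmol/gX/h) at Y = 0.5 g/g."""
    return PirtParameters(y_xs_max=0.5, m_s=0.00703)


@pytest.fixture(scope="session")
def exact_noise() -> NoiseModel:
    return NoiseModel.exact()
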