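import numpy as np
import pytest

from nanoph.calibration import CalibrationModel

#: Buffer series pH values used throughout (the twelve standard targets).
BUFFER_PHS = np.arange(2.5, 8.01, 0.5)


@pytest.fixture
def model():
    """Reference sigmoid: asymptotes 0.2/2.0, pKa 6.5, hillslope 1."""
    return CalibrationModel(
        r_min=0.2, r_max=2.0, pka=6.5, hillslope=1.0, ph_range=(2.5, 8.0)
    )


@pytest.fixture
def acidic_model():
    return CalibrationModel(
        r_min=0.2, r_max=2.0, pka=4.8, hillslope=1.0, ph_range=(2.5, 8.0)
    )
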