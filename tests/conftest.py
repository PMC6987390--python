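import numpy as np
import pytest

import stereoglia as sg


@pytest.fixture(scope="session")
def control_block():
    """Mid-sized control-regime block shared by estimator tests."""
    return sg.build_tissue(sg.CONTROL, (200.0, 200.0, 80.0), seed=101)


@pytest.fixture(scope="session")
def deaff_block():
    return sg.build_tissue(sg.DEAFFERENTED, (150.0, 150.0, 60.0), seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
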