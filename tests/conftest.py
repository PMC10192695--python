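import numpy as np
import pytest

from ictalnet.synthdata import (default_ictal_spec, default_interictal_spec,
                                generate_segment)


@pytest.fixture(scope="session")
def rate():
    return 256


@pytest.fixture(scope="session")
def tvec(rate):
    return np.arange(2560) / rate


@pytest.fixture(scope="session")
def interictal_segment():
    seg, gt = generate_segment(default_interictal_spec(seed=42))
    return seg, gt


@pytest.fixture(scope="session")
def ictal_segment():
    seg, gt = generate_segment(default_ictal_spec(seed=42))
    return seg, gt
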