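import numpy as np
import pytest

from qmri import phantom


@pytest.fixture(scope="session")
def small_acq():
    """Scaled-down acquisition used throughout: full timing, small matrix."""
    return phantom.AcquisitionSpec(matrix=(24, 24, 8))


@pytest.fixture(scope="session")
def tiny_acq():
    return phantom.AcquisitionSpec(matrix=(18, 18, 6))


@pytest.fixture(scope="session")
def tissues():
    return phantom.default_tissues()


@pytest.fixture(scope="session")
def core_tissues(tissues):
    """Meninges + cortex + muscle: the minimal set exercising normalization."""
    return [t for t in tissues if t.label in ("meninges", "cortex", "muscle")]


@pytest.fixture(scope="session")
def labels(small_acq, tissues):
    return phantom.make_label_volume(small_acq, tissues)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
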