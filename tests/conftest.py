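import numpy as np
import pytest

from rbcmat import io


@pytest.fixture(scope="session")
def cohort():
    """The packaged 21-subject paired-means cohort."""
    return io.load_cohort()


@pytest.fixture(scope="session")
def loss_table():
    """The packaged two-subject area/volume/Hb loss table."""
    return io.load_loss_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
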