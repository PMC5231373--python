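import warnings

import numpy as np
import pytest

from droprelax.fixtures import load_table1

warnings.filterwarnings("ignore", category=FutureWarning, module="skimage")


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
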