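import numpy as np
import pytest

from tilegrade.bayes import default_structure
from tilegrade.synthetic import default_generator_cpds


@pytest.fixture
def spec():
    return default_structure()


@pytest.fixture
def gen_cpds(spec):
    return default_generator_cpds(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
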