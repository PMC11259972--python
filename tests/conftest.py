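import numpy as np
import pytest

from hepflow.cluster import build_adjacency
from hepflow.montage import default_montage


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def adjacency(montage):
    return build_adjacency(montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
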