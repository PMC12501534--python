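import numpy as np
import pytest

from wearlimb import quaternions as quat


def random_unit_quats(rng, n):
    return quat.normalize(rng.standard_normal((n, 4)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
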