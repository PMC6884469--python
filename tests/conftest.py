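import numpy as np
import pytest

from fireclass import CriteriaConfig, ISISeries


@pytest.fixture
def cfg():
    return CriteriaConfig()


def make_series(isis, delay=10.0, pfs=10.0, truncated=False):
    return ISISeries(delay=delay, isis=np.asarray(isis, dtype=float),
                     pfs=pfs, truncated=truncated)


@pytest.fixture
def series():
    return make_series
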