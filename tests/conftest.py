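import numpy as np
import pytest

import simms2 as s


@pytest.fixture(scope="session")
def registry():
    return s.builtin_paper_library()


@pytest.fixture
def obs_for():
    """Observation factory: theoretical fragment m/z plus a stated CCS."""

    def _make(seq, series, index, ccs, charge=1):
        f = s.make_fragment(seq, series, index, charge=charge)
        return s.Observation(mz=f.mz, charge=charge, ccs=ccs)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
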