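import numpy as np
import pytest

from fluorkit.traces import FluorescenceTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_trace(values, fs=10.0, t0=0.0):
    return FluorescenceTrace(values=np.asarray(values, dtype=float),
                             sampling_rate=fs, t0=t0)


@pytest.fixture
def trace_factory():
    return make_trace
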