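import numpy as np
import pytest

from hrvguide import RRSeries


@pytest.fixture
def constant_series() -> RRSeries:
    return RRSeries(intervals=np.full(50, 1000.0))


@pytest.fixture
def ramp_series() -> RRSeries:
    """Linear ramp 800, 810, ..., 990 ms (20 beats)."""
    return RRSeries(intervals=np.arange(800.0, 1000.0, 10.0))


def make_series(values) -> RRSeries:
    return RRSeries(intervals=np.asarray(values, dtype=float))
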