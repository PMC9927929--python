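import numpy as np
import pytest
from hypothesis import settings

from clincirc import SampledSeries

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def cosine_series(
    mesor=10.0,
    amplitude=3.0,
    acrophase=6.0,
    period=24.0,
    window=48.0,
    interval=4.0,
    drop_time=None,
    **kwargs,
):
    t = np.arange(0.0, window + 1e-9, interval)
    if drop_time is not None:
        t = t[~np.isclose(t, drop_time)]
    y = mesor + amplitude * np.cos(2 * np.pi * (t - acrophase) / period)
    return SampledSeries("S1", "PER2", t, y, **kwargs)


def ramp_series(slope=1.0, intercept=0.0, window=24.0, interval=4.0):
    t = np.arange(0.0, window + 1e-9, interval)
    return SampledSeries("S1", "ramp", t, intercept + slope * t)


@pytest.fixture
def cosine48():
    return cosine_series()


@pytest.fixture
def cosine24():
    return cosine_series(window=24.0)


@pytest.fixture
def ramp24():
    return ramp_series()
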