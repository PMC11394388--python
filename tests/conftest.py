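import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from fetaldesk.signals import SampleSeries, TriaxialRecord  # noqa: E402


@pytest.fixture
def constant_record():
    """A short record holding constant (0, 0, 1) g at 500 Hz."""
    n, fs = 1500, 500.0
    t = np.arange(n) / fs
    return TriaxialRecord(
        t=t, ax=np.zeros(n), ay=np.zeros(n), az=np.ones(n), fs=fs
    )


def make_series(values, fs=500.0, units="g"):
    return SampleSeries(np.asarray(values, dtype=float), fs, units)


@pytest.fixture
def series_factory():
    return make_series
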