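import numpy as np
import pandas as pd
import pytest

from limbacc.synthetic import CohortConfig
from limbacc.types import AccelTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def tiny_config():
    """A cohort small enough for sub-second generation in unit tests."""
    return CohortConfig(
        n_participants=4,
        nights_per_participant=2,
        night_duration_s=600.0,
        night_duration_jitter=0.0,
        seed=42,
    )


def make_trace(data, fs=30.0, placement="left_ankle", start="2024-01-01 23:00:00"):
    return AccelTrace(
        placement=placement,
        sampling_rate_hz=fs,
        start_time=pd.Timestamp(start),
        data=np.asarray(data, dtype=float),
    )


@pytest.fixture
def quiet_trace():
    """One hour of gravity-only signal with faint sensor noise."""
    fs = 30.0
    n = int(3600 * fs)
    rng = np.random.default_rng(7)
    data = rng.normal(0, 0.005, size=(n, 3))
    data[:, 2] += 1.0
    return make_trace(data, fs=fs)
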