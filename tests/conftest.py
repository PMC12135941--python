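import numpy as np
import pandas as pd
import pytest

from damsleep.series import MinuteSeries


def make_series(
    counts,
    moves=None,
    position=None,
    fly_id="f1",
    t0="2024-01-01 08:00:00",
    led=None,
    completeness=None,
):
    counts = np.asarray(counts)
    n = len(counts)
    if moves is not None and position is None:
        position = np.ones(n, dtype=int)
    return MinuteSeries(
        fly_id=fly_id,
        t0=pd.Timestamp(t0),
        counts=counts,
        light=(np.arange(n) % 1440) < 720,
        led=np.zeros(n) if led is None else np.asarray(led, float),
        moves=None if moves is None else np.asarray(moves),
        position=position,
        completeness=completeness,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
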