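import numpy as np
import pytest

from sleepspike.core import MA, NREM, REM, WAKE, Hypnogram
from sleepspike.synth import SynthConfig, generate_session


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_hypnogram(layout):
    """Build a Hypnogram from [(state, duration_s), ...] starting at t=0."""
    starts, ends, states = [], [], []
    t = 0.0
    for st, d in layout:
        starts.append(t)
        ends.append(t + d)
        states.append(st)
        t += d
    return Hypnogram(np.array(starts), np.array(ends),
                     np.array(states, dtype=object))


@pytest.fixture(scope="session")
def small_session(tmp_path_factory):
    """A 30-min synthetic session shared by IO/pipeline tests."""
    cfg = SynthConfig(duration_s=1800.0, n_units_per_region=4, seed=7,
                      shock_times=(60.0, 90.0), cs_times=(30.0,))
    out = tmp_path_factory.mktemp("session")
    return cfg, generate_session(cfg, out)
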