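import numpy as np
import pytest

from rhythmlab import RhythmSpec, simulate_timecourse, timecourse_from_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noiseless_tc():
    """Exact cosine: mesor 2, amplitude 1, peak ZT12, 7 ZTs x 4 reps."""
    spec = RhythmSpec(mesor=2.0, amplitude=1.0, peak_zt=12.0, sigma=0.0, n_per_zt=4)
    return simulate_timecourse(spec, seed=0)


def make_tc(zt, values, variable="v", condition="control"):
    return timecourse_from_arrays(variable, condition, zt, values)


@pytest.fixture
def make_timecourse():
    return make_tc
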