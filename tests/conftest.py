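import numpy as np
import pytest
from hypothesis import settings

import nirsbmi as nb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def single_schedule():
    """Default one-level session: 146 s baseline + 10 x (20 s task + 20 s rest)."""
    return nb.build_default_paradigm()


@pytest.fixture(scope="session")
def dual_schedule():
    """Two-level session with the 25 s inter-level delay."""
    return nb.build_default_paradigm(levels=["mwl1", "mwl2"])


@pytest.fixture(scope="session")
def default_subject(dual_schedule):
    """One simulated subject (seed 1) with its filtered concentration series."""
    recording, truth = nb.simulate_subject(nb.SubjectConfig(seed=1), dual_schedule)
    series = nb.lowpass(nb.invert_mbll(recording))
    return recording, truth, series


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
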