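import numpy as np
import pytest

from vigilfc import synthetic as syn


@pytest.fixture(scope="session")
def tiny_study():
    """4 subjects, short sessions: enough for pipeline smoke tests."""
    cfg = syn.StudyConfig(n_subjects=5, duration_s=630,
                          transition_rate=0.005)
    return syn.generate_study(cfg, seed=123)


@pytest.fixture(scope="session")
def default_study():
    """The default 20-subject study used by the end-to-end checks."""
    return syn.generate_study(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
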