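import numpy as np
import pytest
from hypothesis import settings

from cvemp.synthetic_data import GeneratorConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def paper_config():
    """The shipped study-design preset."""
    return GeneratorConfig.paper2025(seed=7)


@pytest.fixture
def small_config():
    """A reduced design for fast epoch-level tests: 2+2 participants,
    short schedule, few epochs."""
    return GeneratorConfig.paper2025(
        n_women=2, n_men=2, epochs_per_sequence=40, seed=7,
        level_series=(40, 38, 36, 34, 39, 37),
    )


@pytest.fixture
def noiseless_config():
    """Deterministic waveforms: no jitter, no artifacts; background kept for
    the amplitude scale but additive noise suppressed by the template's size."""
    return GeneratorConfig.paper2025(
        n_women=1, n_men=1, artifact_prob=0.0, jitter_sd=0.0, seed=7,
    )
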