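import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssvepclean import SynthConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects, 20-s sessions, default (artifact-heavy) conditions."""
    cfg = SynthConfig(n_subjects=3, session_s=20.0, seed=7)
    dataset, truths = generate_dataset(cfg)
    return dataset, truths


@pytest.fixture(scope="session")
def quiet_dataset():
    """3 subjects, artifact-free, low background: an easy SSVEP task."""
    cfg = SynthConfig(
        n_subjects=3, session_s=20.0, seed=11, background_rms=1.0
    ).artifact_free()
    dataset, _ = generate_dataset(cfg)
    return dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
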