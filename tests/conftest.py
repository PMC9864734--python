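import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from heathazard.synthetic import EpisodeTruth, SyntheticConfig, generate_grid


@pytest.fixture(scope="session")
def demo_config():
    """Small 30-year grid with three true episodes and one decoy."""
    episodes = [
        EpisodeTruth(target=(0, 0), year=1995, start=40, duration=5),
        EpisodeTruth(target=(1, 2), year=2000, start=100, duration=3),
        EpisodeTruth(target=(2, 1), year=2010, start=60, duration=8),
        EpisodeTruth(target=(3, 3), year=1992, start=10, duration=2),  # decoy
    ]
    return SyntheticConfig(seed=42, shape=(4, 4), episodes=episodes)


@pytest.fixture(scope="session")
def demo_grid(demo_config):
    return generate_grid(demo_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
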