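import numpy as np
import pytest

from drivewave import DriveSystem, ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A miniature landscape that keeps full runs to a fraction of a second."""
    return ScenarioConfig(
        drive_system=DriveSystem.X_SHREDDER,
        R=6.0,
        sigma=8.0,
        landscape_length=500.0,
        wt_init_range=(50.0, 250.0),
        intro_position=50.0,
        max_generations=200,
        seed=7,
    )
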