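import numpy as np
import pytest

from blazedtrail import SynthSpec, build_grid_environment, build_line_environment


@pytest.fixture
def line5_correct():
    return build_line_environment(5, 1.0, seed=0)


@pytest.fixture
def line3_flip():
    return build_line_environment(3, 0.0, "flip", seed=0)


@pytest.fixture
def grid5_correct():
    return build_grid_environment(5, 1.0, seed=0)


@pytest.fixture
def synth_spec():
    return SynthSpec(seed=11)


@pytest.fixture
def straight_track():
    """Load moving due east at 1 cm/s for 100 s, 50 Hz."""
    from blazedtrail import Trajectory

    t = np.arange(0, 100, 0.02)
    return Trajectory(id="load", t=t, x=t * 1.0, y=np.zeros_like(t), frame_rate=50.0)
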