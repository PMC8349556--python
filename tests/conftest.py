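import numpy as np
import pytest

from condensekit import simulate


@pytest.fixture
def small_scene():
    """A 2-cell scene that crosses Csat midway through the ramp."""
    cfg = simulate.SceneConfig(n_cells=2, n_frames=25, seed=7)
    return simulate.simulate_scene(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
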