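import numpy as np
import pytest

from cardiomap import FluorescenceMovie, SimulationSpec, simulate_paced_movie


@pytest.fixture
def mouse_spec():
    """Noise-free mouse whole-heart-like planar pacing run."""
    return SimulationSpec(seed=0)


@pytest.fixture
def clean_movie(mouse_spec):
    """Noise-free synthetic movie plus its ground truth."""
    return simulate_paced_movie(mouse_spec)


@pytest.fixture
def noisy_movie():
    spec = SimulationSpec(noise_sd=0.05, seed=7)
    return simulate_paced_movie(spec)


def make_movie(data, frame_rate=1000.0, pixel_size=100.0, polarity="upright"):
    return FluorescenceMovie(data=np.asarray(data, dtype=float),
                             frame_rate=frame_rate, pixel_size=pixel_size,
                             polarity=polarity)


@pytest.fixture
def tiny_movie():
    """4-frame 3x3 movie with deterministic values."""
    rng = np.random.default_rng(0)
    return make_movie(rng.normal(size=(40, 3, 3)))
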