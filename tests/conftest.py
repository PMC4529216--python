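import numpy as np
import pytest
from hypothesis import settings

from frfres import make_formant_grid, make_ground_truth, simulate_trials

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    """The default 10-20 kHz, 0.1-octave formant grid (11 centers, 55 pairs)."""
    return make_formant_grid()


@pytest.fixture(scope="session")
def manifest(grid):
    return grid.manifest()


@pytest.fixture(scope="session")
def noise_table(grid):
    """A structured LN-Poisson site: smoothed-noise tuning, 15 repeats."""
    gt = make_ground_truth("smoothed_noise", {"w": 0.2, "amplitude": 50.0},
                           grid=grid, seed=42)
    return simulate_trials(gt, n_repeats=15, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def flat_table(grid):
    """A null site: constant background firing, no evoked modulation."""
    gt = make_ground_truth("flat", {"rate": 0.0}, grid=grid)
    return simulate_trials(gt, n_repeats=15, rng=np.random.default_rng(7))
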