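import numpy as np
import pytest

from pin1dyn import synthetic_data


@pytest.fixture(scope="session")
def small_ensemble():
    """Two-state toy ensemble shared across geometry/cluster tests."""
    top, frames, truth = synthetic_data.gen_two_state_ensemble(
        p_compact=0.5, n_frames=600, seed=11
    )
    return top, frames, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
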