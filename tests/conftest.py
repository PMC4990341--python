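import numpy as np
import pytest

from seqfx import PopulationSpec, generate_population


@pytest.fixture(scope="session")
def het_population():
    """30 participants x 1000 trials: heterogeneous mean-zero lag-1 effect
    plus a common lag-3 alternation bias, with ground-truth coefficients."""
    spec = PopulationSpec(
        n_participants=30,
        n_trials=1000,
        L_gen=3,
        beta_mean=[0.0, 0.0, 0.0, -0.4],
        beta_sd=[0.0, 1.0, 0.0, 0.0],
        seed=20240901,
    )
    return generate_population(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
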