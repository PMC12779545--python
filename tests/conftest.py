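import numpy as np
import pytest

from movenc import synth


@pytest.fixture(scope="session")
def small_session():
    """A small rendered session shared by read-only tests."""
    rng = np.random.default_rng(7)
    specs = synth.population(4, "movement_linear", rng, coupling_gain=6.0,
                             baseline_rate=10.0)
    specs += synth.population(2, "untuned", rng, baseline_rate=8.0)
    cfg = synth.desk_config(n_trials=30, seed=7, neuron_specs=tuple(specs))
    return synth.simulate_session(cfg)
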