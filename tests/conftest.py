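import numpy as np
import pytest

import rhythmfit as rf


@pytest.fixture
def dense_times():
    """Circadian design: 24 timepoints every 2 h over 48 h, 2 replicates."""
    return np.repeat(np.arange(0.0, 48.0, 2.0), 2)


@pytest.fixture
def fit_config():
    return rf.FitConfig()


@pytest.fixture
def small_mixed_panel():
    """5 features per class (incl. null) at 5% relative noise, seeded."""
    spec = rf.SimulationSpec(n_per_class=5, noise_rel=0.05, noise_sd=0.1, seed=1234)
    return rf.simulate_panel(spec)
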