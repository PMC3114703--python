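import numpy as np
import pytest

from microloop import SimulationParams, make_bundle


@pytest.fixture
def quiet_params():
    """Noise-free generator parameters with simple round-number rates."""
    return SimulationParams(mu_b=0.5, delta_v=0.1, graze=0.2, enrich=0.3,
                            autotroph_boost=0.1, decay_v=0.0, cv_noise=0.0,
                            bacteria0=1.0e6, viruses0=5.0e7, seed=7)


@pytest.fixture
def quiet_bundle(quiet_params):
    """Full noise-free bundle over the standard 0/48/96 h design."""
    return make_bundle(quiet_params, replicates=3, label="SIM",
                       assay_days=(0, 2, 4))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
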