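import numpy as np
import pytest

import emtres as em
from emtres.scoring import score_ensemble


@pytest.fixture(scope="session")
def default_topology():
    return em.load_default_topology()


@pytest.fixture(scope="session")
def toggle():
    return em.make_toggle_fixture()


@pytest.fixture(scope="session")
def medium_scored(default_topology):
    """A 400-set scored ensemble shared by the scoring-level tests."""
    rng = np.random.default_rng(2024)
    scores, stats, thresholds = score_ensemble(
        default_topology, em.SamplingRanges(), n_sets=400, n_init=100, rng=rng
    )
    return scores, stats, thresholds


@pytest.fixture(scope="session")
def sampled_params(default_topology):
    """A handful of kinetic parameter sets for integrator-level tests."""
    rng = np.random.default_rng(9)
    ens = em.sample_parameter_sets(default_topology, em.SamplingRanges(), 6, rng)
    return [ens[i] for i in range(len(ens))]
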