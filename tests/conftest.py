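import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def small_sim_truth():
    """A small simulated study (5 families) shared across pipeline tests."""
    from mirevol.synthetic_data import SimParams, evolve_along_tree

    return evolve_along_tree(SimParams(n_families=5, rng_seed=11))
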