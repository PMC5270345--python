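import numpy as np
import pytest

from plumavis.spectra import GRID_5NM, ReflectanceSpectrum
from plumavis.visual_model import build_visual_system


@pytest.fixture(scope="session")
def vs():
    """Default V-type visual system (average violet-sensitive observer)."""
    return build_visual_system()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def flat_spectrum():
    def make(level=50.0):
        return ReflectanceSpectrum(GRID_5NM.copy(), np.full(GRID_5NM.size, level))

    return make


@pytest.fixture(scope="session")
def random_spectrum():
    def make(seed, low=5.0, high=80.0):
        r = np.random.default_rng(seed)
        return ReflectanceSpectrum(GRID_5NM.copy(), r.uniform(low, high, GRID_5NM.size))

    return make


@pytest.fixture(scope="session")
def small_posterior():
    """A 15-species tree posterior with a 9-subspecies grafting table."""
    from plumavis import synthetic

    return synthetic.gen_tree_posterior(
        n_species=15, n_trees=20, jitter=0.05, nni_prob=0.1,
        n_subspecies=9, seed=11,
    )
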