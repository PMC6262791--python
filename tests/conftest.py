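import numpy as np
import pytest

from opticmorph import synthetic
from opticmorph.abacus import AbacusParams

# detection parameters suited to the default synthetic scene (nuclear
# sigma 1.8 µm, amplitudes 160-230, noise_sd <= 10)
SCENE_PARAMS = AbacusParams(sigma_xy=2.0, L=20.0, h=30.0)


@pytest.fixture(scope="session")
def small_volume_truth():
    """50 well-separated nuclei in a 40x192x192 stack, noise_sd=5, seed=1."""
    placed = synthetic.random_well_separated_nuclei(50, (40, 192, 192), seed=1)
    return synthetic.SyntheticVolumeTruth(placed.nuclei, placed.dx, placed.dz, 5.0, 1)


@pytest.fixture(scope="session")
def small_volume(small_volume_truth):
    grids = synthetic.make_nuclei_volume(small_volume_truth, (40, 192, 192))
    return grids["green"]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
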