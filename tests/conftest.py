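import matplotlib

matplotlib.use("Agg")

import pytest

from gazecontrast import simulate
from gazecontrast.density import GridSpec


@pytest.fixture(scope="session")
def small_experiment():
    """A complete but desk-sized synthetic session (4 participants, 8
    trials/block), shared read-only across tests."""
    cfg = simulate.default_config(n_participants=4, trials_per_block=8, seed=11)
    ds, truth = simulate.generate_experiment(cfg)
    return ds, truth, cfg


@pytest.fixture(scope="session")
def small_dataset(small_experiment):
    return small_experiment[0]


@pytest.fixture
def small_grid():
    """Coarse grid covering the synthetic fixation cloud."""
    return GridSpec(x_min=0.0, x_max=6.4, y_min=-5.2, y_max=1.2, resolution=0.1)
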