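import numpy as np
import pytest

from flimforge.axes import TimeAxis, default_axis
from flimforge.irf import delta_irf
from flimforge.simulate import two_region_fixture


@pytest.fixture(scope="session")
def axis() -> TimeAxis:
    return default_axis()


@pytest.fixture(scope="session")
def delta(axis):
    return delta_irf(axis)


@pytest.fixture(scope="session")
def short_axis() -> TimeAxis:
    """Coarse 64-bin axis with the same 25 ns span as the default grid."""
    return TimeAxis(bin_width=0.3908, n_bins=64)


@pytest.fixture(scope="session")
def two_region_dataset():
    """64 easy two-region images (1 ns / 4 ns) on the coarse axis."""
    data = two_region_fixture(64, seed=5)
    return [d[0] for d in data], [d[1] for d in data]


@pytest.fixture(scope="session")
def trained_results(two_region_dataset):
    """Three independently seeded fits of the small network on the
    two-region dataset (shared across learning-behaviour tests)."""
    from flimforge.network import LifetimeRegressionModel, NetworkConfig, TrainingConfig

    stacks, maps = two_region_dataset
    results = []
    for seed in (0, 1, 2):
        model = LifetimeRegressionModel(
            stacks, maps,
            network_config=NetworkConfig(in_time_bins=stacks[0].axis.n_bins,
                                         width_multiplier=0.25, seed=seed),
            training_config=TrainingConfig(max_epochs=50, seed=seed),
        )
        results.append(model.fit())
    return results


@pytest.fixture
def rng():
    return np.random.default_rng(42)
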