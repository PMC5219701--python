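import numpy as np
import pytest

from bloodmix import CompositionModel, SimulationConfig
from bloodmix.simulate import simulate_dataset, simulate_test_set


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_features=120, n_samples=60, markers_per_type=4,
                            seed=5)


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def recovery_study():
    """The full parameter-recovery study: default-size simulation
    (500 features, 150 training samples, 30 planted markers, mixture
    noise 0.2, label noise 0.03), tuned model over the standard alpha
    grid, plus a 50-sample held-out set from the same signatures.

    Session-scoped because tuning is the expensive step; several tests
    interrogate different aspects of the same fitted study.
    """
    cfg = SimulationConfig(seed=11)
    ds = simulate_dataset(cfg)
    results = CompositionModel(ds.expression, ds.silver).fit_cv(
        k=10, seed=7, n_lambda=100)
    test = simulate_test_set(cfg, n_samples=50, seed=18)
    return {"config": cfg, "train": ds, "results": results, "test": test}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
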