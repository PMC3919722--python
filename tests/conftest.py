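import numpy as np
import pytest

import evacdyn as e


class ConstantRateModel:
    """Rate law that ignores all covariates (testing aid)."""

    def __init__(self, r: float):
        self.r = r

    def rate(self, q, capacity=None, window=None):
        return self.r


@pytest.fixture
def constant_model_factory():
    return ConstantRateModel


@pytest.fixture(scope="session")
def small_experiment():
    """A 40-run synthetic experiment from the default population model."""
    pool = e.default_trajectory_pool(seed=11)
    design = e.make_design(n_runs=40, trajectory_pool=pool, seed=11)
    logs, manifest = e.generate_experiment(design, e.DEFAULT_POPULATION_MODEL, rng_seed=11)
    return design, logs, manifest


@pytest.fixture(scope="session")
def small_panel(small_experiment):
    _, logs, _ = small_experiment
    return e.build_indicators(logs)
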