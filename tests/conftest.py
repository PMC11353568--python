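import numpy as np
import pytest

from mismatchnet import RunConfig, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_dataset():
    """3 families x 30 lines, 60 markers, 2 environments, one trait."""
    cfg = SimulationConfig(n_families=3, lines_per_family=30, p=60,
                           n_qtl=10, h2=0.5, n_envs=2, traits=("t1",),
                           seed=3)
    return simulate_dataset(cfg)


@pytest.fixture
def fast_config():
    """Small CV budget for toy-scale benchmark runs."""
    return RunConfig(cv_folds=4, n_lambda=25, tol=1e-5, seed=7,
                     models=("lasso", "wlasso"))


def random_instance(rng, n=None, p=None):
    """Random small regression instance with finite random weights."""
    n = n or int(rng.integers(20, 41))
    p = p or int(rng.integers(2, 11))
    X = rng.normal(size=(n, p)) * rng.uniform(0.5, 2.0, p)
    beta = rng.normal(size=p) * (rng.random(p) < 0.7)
    y = X @ beta + rng.normal(scale=0.5, size=n)
    w = rng.uniform(0.3, 3.0, p)
    return X, y, w
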