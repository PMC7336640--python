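import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from qlcox import (
    FitControl,
    QuasiLinearParams,
    SurvivalDataset,
    generate_dataset,
    scenario_catalog,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_dataset(rng, n=20, p=2, censor_frac=0.3):
    """Small random survival dataset with distinct times."""
    time = rng.uniform(0.5, 10.0, size=n)
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[0] = 1
    X = rng.normal(size=(n, p))
    return SurvivalDataset(time, event, X)


def random_params(rng, K=2, p=2, scale=0.6):
    pi = rng.dirichlet(np.full(K, 5.0))
    beta = rng.normal(scale=scale, size=(K, p))
    return QuasiLinearParams(pi, beta)


@pytest.fixture
def small_data(rng):
    return random_dataset(rng, n=12, p=2)


@pytest.fixture
def small_params(rng):
    return random_params(rng, K=2, p=2)


@pytest.fixture
def scenario1():
    return scenario_catalog()["1-IS"]


@pytest.fixture
def scenario1_data(scenario1):
    return generate_dataset(scenario1, seed=42)


@pytest.fixture
def fast_control():
    return FitControl(n_restarts=2, tol=1e-8, max_outer_iter=300, seed=0)
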