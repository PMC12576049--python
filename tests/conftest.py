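import numpy as np
import pandas as pd
import pytest

from survexplain import (AnalyticModel, SurvivalDataset, TimeGrid)


def make_dataset(times, events, features=None):
    n = len(times)
    if features is None:
        features = pd.DataFrame({"x": np.arange(n, dtype=float)})
    return SurvivalDataset(features, np.asarray(times, float),
                           np.asarray(events, int))


@pytest.fixture
def tiny_dataset():
    return make_dataset([1.0, 2.0, 3.0], [1, 0, 1])


@pytest.fixture
def random_censored_dataset():
    rng = np.random.default_rng(42)
    n = 80
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    T = rng.exponential(2.0, n) * np.exp(-0.5 * X["x1"].to_numpy())
    C = rng.exponential(3.0, n)
    times = np.minimum(T, C)
    events = (T <= C).astype(int)
    return SurvivalDataset(X, np.maximum(times, 1e-6), events)


@pytest.fixture
def exp_hazard_model():
    """Exponential PH oracle: S(t|x) = exp(-t * exp(x1))."""
    return AnalyticModel(
        lambda t, X: np.exp(-np.outer(np.exp(X["x1"].to_numpy()), t)))


@pytest.fixture
def grid_1to4():
    return TimeGrid([1.0, 2.0, 3.0, 4.0])
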