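import numpy as np
import pandas as pd
import pytest

import survfunnel as sf


@pytest.fixture
def tiny_cohort():
    """Four subjects, two centers, one covariate, horizon 12 months."""
    df = pd.DataFrame(
        {
            "center": ["A", "A", "B", "B"],
            "time": [3.0, 12.0, 5.0, 9.0],
            "status": [1, 0, 0, 1],
            "age": [0.5, -0.2, 1.0, 0.0],
        }
    )
    return sf.Cohort(df, ["age"], 12.0)


def _random_cohort(rng, n_centers=6, size=25, horizon=12.0):
    n = n_centers * size
    center = np.repeat(np.arange(n_centers), size)
    x = rng.normal(0, 0.5, n)
    t_event = rng.exponential(1.0, n) / (0.06 * np.exp(x))
    t_cens = rng.exponential(1.0, n) / 0.04
    time = np.minimum(np.minimum(t_event, t_cens), horizon)
    status = ((t_event <= t_cens) & (t_event <= horizon)).astype(int)
    df = pd.DataFrame({"center": center, "time": time, "status": status, "x": x})
    return sf.Cohort(df, ["x"], horizon)


@pytest.fixture
def sim_cohort():
    """A ~150-subject truncated multi-center cohort with realistic censoring."""
    return _random_cohort(np.random.default_rng(42))


@pytest.fixture
def make_cohort():
    """Factory for randomized cohorts with a chosen seed/shape."""

    def factory(seed=0, **kw):
        return _random_cohort(np.random.default_rng(seed), **kw)

    return factory
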