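import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rivermetab import SyntheticConfig, simulate_site
from rivermetab.synthetic import truth_frame

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_site():
    """Six noisy synthetic days at the default study conditions."""
    cfg = SyntheticConfig(n_days=6, seed=42)
    forcing, truth = simulate_site(cfg)
    return cfg, forcing, truth


@pytest.fixture(scope="session")
def noise_free_site():
    """Six noise-free synthetic days (exact forward/inverse checks)."""
    cfg = SyntheticConfig(n_days=6, seed=42, sigma_obs=0.0, sigma_proc=0.0)
    forcing, truth = simulate_site(cfg)
    return cfg, forcing, truth


@pytest.fixture(scope="session")
def truth_df():
    def _make(truth):
        return truth_frame(truth)

    return _make


def k600_series(truth):
    tf = truth_frame(truth)
    return pd.Series(tf["K600_true"].to_numpy(), index=tf.index)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
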