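import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctocc.fit import fit_mle
from ctocc.simulate import scaled_config, scaled_spec, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """40-site scaled synthetic dataset with a nonzero interaction."""
    cfg = scaled_config(n_sites=40, seed=7)
    ds, truth = simulate_dataset(cfg)
    return ds, truth, cfg


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """One ML fit of the small dataset, shared across tests."""
    ds, truth, cfg = small_dataset
    spec = scaled_spec(seed=1)
    return fit_mle(ds, spec), ds, cfg, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
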