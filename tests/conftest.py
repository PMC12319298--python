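import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Reduced replicate of the default study conditions: same imbalance
    structure and scaling truths, fewer trees and a lower conduit cap so the
    resampling loops stay fast."""
    from xyloscale import synthetic
    return synthetic.GeneratorConfig(
        n_species=3, n_trees_per_species=2,
        count_model=synthetic.CountModel(max_count=1500), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    from xyloscale import synthetic
    return synthetic.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_metrics(small_dataset):
    from xyloscale import anatomy
    return anatomy.conduit_metrics(small_dataset)


def rng(seed=0):
    return np.random.default_rng(seed)
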