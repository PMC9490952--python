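import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from curupira.pipeline import RunConfig, default_truth  # noqa: E402


@pytest.fixture(scope="session")
def small_config():
    """A fast study layout: 4 contigs x 20 kb, 3 clusters, 1 B contig."""
    return RunConfig(
        n_contigs=4,
        contig_length=20_000,
        n_clusters=3,
        n_b_contigs=1,
        b_multiplier=3.0,
        srna_reads=20_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return default_truth(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
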