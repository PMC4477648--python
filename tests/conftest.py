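import pytest
from hypothesis import HealthCheck, settings

from slqscan.io import bundled_oligos
from slqscan.synthetic import SyntheticConfig, generate_synthetic_genome

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def oligos():
    return bundled_oligos()


@pytest.fixture(scope="session")
def small_synthetic():
    """A 120-kb synthetic genome shared across tests (cheap to scan)."""
    config = SyntheticConfig(
        length=120_000, n_slqs=6, n_pqs7=4, n_decoys=6, n_genes=5, seed=11
    )
    record, truth, genes = generate_synthetic_genome(config)
    return config, record, truth, genes
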