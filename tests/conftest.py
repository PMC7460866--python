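import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from irmutscan.synthetic_data import (  # noqa: E402
    SimulationConfig,
    make_reference,
    make_translocations,
    make_variant_sets,
)


@pytest.fixture(scope="session")
def small_config():
    """One treated sample, 4 x 300 kb chromosomes, 5,000 variants."""
    return SimulationConfig(
        seed=11,
        chrom_lengths=(300_000, 300_000, 300_000, 300_000),
        n_variants_per_sample=5_000,
        sample_labels=("16h_2Gy",),
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return make_reference(small_config)


@pytest.fixture(scope="session")
def small_variant_sets(small_config, small_reference):
    return make_variant_sets(small_config, small_reference)


@pytest.fixture(scope="session")
def small_translocations(small_config):
    return make_translocations(small_config)
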