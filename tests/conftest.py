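import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hrsig import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signature cohort shared by read-only tests."""
    cfg = GeneratorConfig(
        n_per_site_per_group=10,
        n_sites=3,
        n_networks=6,
        n_units=80,
        signature_networks=(0, 1, 2),
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted signal (shared, read-only)."""
    cfg = GeneratorConfig(
        n_per_site_per_group=15,
        n_sites=2,
        n_networks=2,
        n_units=60,
        carrier_fraction=0.0,
        signature_networks=(),
        signature_shift=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
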