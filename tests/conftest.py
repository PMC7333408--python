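import pytest
from hypothesis import HealthCheck, settings

from hostblock import (
    TABLE1_18SV4,
    default_oyster_spec,
    simulate_reference_db,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def oyster_db():
    """Planted-truth fixture: host clade with the conserved blocking motif
    plus three motif-free protist clades."""
    records, truths = simulate_reference_db(default_oyster_spec(seed=7))
    return records, truths


@pytest.fixture(scope="session")
def v4():
    return TABLE1_18SV4
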