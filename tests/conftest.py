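import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    """Seeded stdlib RNG for reproducible random instances."""
    return random.Random(20240917)


def random_string(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(n))
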