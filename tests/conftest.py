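import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    """Seeded stdlib RNG for ad-hoc random fixtures."""
    return random.Random(20130610)


@pytest.fixture
def random_sense_codon(rng):
    from mkalpha.codons import SENSE_CODONS

    def draw():
        return rng.choice(SENSE_CODONS)

    return draw
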