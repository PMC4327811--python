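import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spacedist import DnaSequence, PatternSet, parse_pattern

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def pattern_1101():
    return parse_pattern("1101")


@pytest.fixture
def toy_pair():
    """The worked-example pair with a unique 1101-match at (3, 1)."""
    return DnaSequence("S1", "ACTACAG"), DnaSequence("S2", "TATAGG")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, L, id="seq", ambiguity_prob=0.0):
    """Random test sequence, optionally sprinkled with N characters."""
    chars = rng.choice(list("ACGT"), size=L)
    if ambiguity_prob > 0:
        mask = rng.random(L) < ambiguity_prob
        chars[mask] = "N"
    return DnaSequence(id, "".join(chars))


def single_pattern_set(text):
    return PatternSet((parse_pattern(text),))
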