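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

from nsltp import ProteinSequence, builtin_patterns


@pytest.fixture(scope="session")
def builtins():
    return builtin_patterns()


@pytest.fixture()
def rng():
    return random.Random(2024)


def make_scaffold(gaps, n_offset=2, c_tail=5, cxc_x="N", spacer="A"):
    """Assemble an 8-Cys scaffold sequence from explicit spacing."""
    g1, g2, g3, g4, g5 = gaps
    return ProteinSequence(
        "scaffold",
        spacer * n_offset
        + "C" + spacer * g1
        + "C" + spacer * g2
        + "CC" + spacer * g3
        + "C" + cxc_x + "C" + spacer * g4
        + "C" + spacer * g5
        + "C" + spacer * c_tail,
    )
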