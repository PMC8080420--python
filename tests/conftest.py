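import random

import pytest
from hypothesis import HealthCheck, settings

from softbidist import table4_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table4_rows():
    return table4_fixture()


@pytest.fixture(scope="session")
def regression_rows(table4_rows):
    """The 13 fixture rows safe for regression (anomalous row excluded)."""
    return [r for r in table4_rows if not r.anomalous]


@pytest.fixture()
def rng():
    return random.Random(20240917)


def random_word(rng, alphabet="abcd", max_len=8, min_len=0):
    return "".join(
        rng.choice(alphabet) for _ in range(rng.randint(min_len, max_len))
    )
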