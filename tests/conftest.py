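import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mxetools import seqcore

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def enzymes():
    """The bundled enzyme table."""
    return seqcore.builtin_enzymes()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
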